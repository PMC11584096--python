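"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is a literal, line-by-line transcription of the published
pseudocode or a textbook formula, deliberately sharing no code with the
package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_AAS = tuple("ACDEFGHIKLMNPQRSTVWY")


def blosum_norm(a: str, b: str) -> float:
    row_max = max(float(_B62[a][x]) for x in _AAS)
    return float(_B62[a][b]) / row_max


def position_type_oracle(r_t, s_t, r_c, s_c, r_r, s_r, thr1, thr2, thr_bls):
    """Literal transcription of the six-category typing pseudocode.

    Returns (category, type, score).
    """
    GAP = "-"
    ssum = s_t + s_c + s_r
    inv = 1.0 / ssum
    # category 1: R_c = R_r and they are gap
    if r_c == r_r and r_c == GAP:
        if r_t == GAP:
            return 1, "II", inv
        return 1, "I", ssum
    # category 2: R_T is gap
    if r_t == GAP:
        if r_c == GAP or r_r == GAP:
            return 2, "II", inv
        return 2, "I", ssum
    # category 3: R_T != R_c != R_r (all pairwise distinct)
    if r_t != r_c and r_c != r_r and r_t != r_r:
        if r_t != GAP and r_r != GAP and r_c != GAP:
            if s_t >= thr1 and s_c >= thr2 and s_r >= thr2:
                return 3, "I", ssum
            if blosum_norm(r_t, r_c) <= thr_bls and blosum_norm(r_t, r_r) <= thr_bls:
                return 3, "I", ssum
            return 3, "IV", ssum
        if r_c == GAP:
            if s_t >= thr1 and s_r >= thr2:
                return 3, "I", ssum
            if blosum_norm(r_t, r_r) <= thr_bls:
                return 3, "I", ssum
            return 3, "IV", ssum
        if r_r == GAP:
            if s_t >= thr1 and s_c >= thr2:
                return 3, "I", ssum
            if blosum_norm(r_t, r_c) <= thr_bls:
                return 3, "I", ssum
            return 3, "IV", ssum
    # category 4: R_T = R_c
    if r_t == r_c:
        return 4, "II", inv
    # category 5: R_T != R_c and R_T = R_r
    if r_t != r_c and r_t == r_r:
        if r_c == GAP:
            return 5, "III", ssum
        if blosum_norm(r_t, r_c) <= thr_bls and s_c >= thr2:
            return 5, "III", ssum
        return 5, "II", inv
    # category 6: R_T != R_c and R_c = R_r
    if r_t != r_c and r_c == r_r:
        if s_t >= thr1 and s_c >= thr2 and s_r >= thr2:
            return 6, "I", ssum
        if blosum_norm(r_t, r_c) <= thr_bls:
            return 6, "I", ssum
        return 6, "II", inv
    raise AssertionError("unreachable representative pattern")


def weights_oracle(types, scores, c1, c3_mode, c3_const, c4_mode, c4_const,
                   double_type1):
    """Literal transcription of the type-chained weighting pseudocode."""
    types = list(types)
    scores = list(scores)
    n = len(types)
    w = [0.0] * n
    s1 = [scores[i] for i in range(n) if types[i] == "I"]
    if not s1:
        raise ValueError("no type I positions")
    for i in range(n):
        if types[i] == "I":
            w[i] = scores[i] / min(s1) * c1
    c2 = sum(w[i] for i in range(n) if types[i] == "I") / len(s1)
    s4 = [scores[i] for i in range(n) if types[i] == "IV"]
    for i in range(n):
        if types[i] == "IV":
            w[i] = scores[i] / max(s4) * c2
    if c3_mode == "const":
        c3 = c3_const
    elif not s4:
        c3 = 0.5
    elif c3_mode == "min_type4":
        c3 = min(w[i] for i in range(n) if types[i] == "IV")
    else:
        c3 = min(w[i] for i in range(n) if types[i] == "IV") / 2.0
    s3 = [scores[i] for i in range(n) if types[i] == "III"]
    for i in range(n):
        if types[i] == "III":
            w[i] = scores[i] / max(s3) * c3
    if c4_mode == "const":
        c4 = c4_const
    elif not s3:
        c4 = 0.2
    else:
        c4 = min(w[i] for i in range(n) if types[i] == "III") / 2.0
    s2 = [scores[i] for i in range(n) if types[i] == "II"]
    for i in range(n):
        if types[i] == "II":
            w[i] = scores[i] / max(s2) * c4
    if double_type1:
        for i in range(n):
            if types[i] == "I":
                w[i] *= 2.0
    return w


def sdp_oracle(a_t, p_t, others):
    """Literal transcription of the per-position SDP pseudocode."""
    acc = 0.0
    p_at_values = []
    for (a_i, p_i_ai, p_i_at, d_i) in others:
        cons = -(p_i_ai <= 0.5) + (p_i_ai > 0.5)
        s_i = 0.0
        if cons == 1 and a_i == a_t:
            s_i = -math.exp(p_i_at)
        elif (cons == -1 and a_i == a_t) or a_i != a_t:
            s_i = math.exp(1) - math.exp(p_i_ai)
        acc += s_i / d_i
        p_at_values.append(p_i_at)
    omega = 1.0 - max(p_at_values)
    return (math.exp(p_t) + omega * acc) * p_t


def auroc_oracle(y, scores):
    """Rank statistic: fraction of (positive, negative) pairs ordered
    correctly, ties counting one half."""
    y = np.asarray(y)
    s = np.asarray(scores, float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def welch_oracle(a, b):
    """Textbook Welch statistic with Welch-Satterthwaite degrees of freedom."""
    from scipy.special import stdtr

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return t, p
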