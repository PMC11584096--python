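"""Subfamily-specific profile weighting and scoring.

A subfamily-specific profile starts from plain observed column frequencies of
the target subfamily's (reference-gap-removed) alignment — no pseudocount
priors.  Each column then receives a weight reflecting how well it separates
the *target* subfamily from its *closest* phylogenetic neighbour and from the
*rest* of the superfamily:

1. per column, a representative symbol and score are chosen for each of the
   three groups from the column frequency vectors (Step 1);
2. the column is placed into one of six categories and one of four types
   (I, II, III, IV) by comparing the representatives, their conservation
   levels and row-normalized BLOSUM62 similarities (Step 2); the initial
   score is the sum of group scores (types I/III/IV) or its reciprocal
   (type II);
3. final weights chain the types together: type I columns anchor the scale
   (weight >= c1), type IV is capped by the mean type-I weight, type III and
   II by constants or fractions of the preceding type's minimum, depending on
   the subfamily preset.

Scoring multiplies each column's log-odds contribution by its weight, so a
weight of 1 leaves the column untouched, large weights amplify
target-specific columns and small weights silence columns shared across
subfamilies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS, AA_INDEX, GAP, SYMBOLS, SYMBOL_INDEX
from .io_core import Alignment

logger = logging.getLogger(__name__)

TYPE_I, TYPE_II, TYPE_III, TYPE_IV = "I", "II", "III", "IV"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupingScheme:
    """Disjoint target / closest / rest subfamily groups."""

    target: tuple[str, ...]
    closest: tuple[str, ...]
    rest: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [set(self.target), set(self.closest), set(self.rest)]
        if any(not g for g in groups):
            raise ValueError("target, closest and rest must all be non-empty")
        if groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2]:
            raise ValueError("target, closest and rest must be disjoint")


@dataclass(frozen=True)
class WeightConstants:
    """Thresholds and per-subfamily weighting constants.

    ``c3_mode`` / ``c4_mode`` select how the type III / type II weight caps
    are derived: a fixed constant, the minimum weight of the preceding type,
    or half of it.  ``double_type1`` doubles type-I weights after all caps
    are resolved (used for GPRC6A).
    """

    thr1: float = 0.8
    thr2: float = 0.8
    thr_bls: float = 0.5
    c1: float = 1.0
    c3_mode: str = "const"          # const | min_type4 | half_min_type4
    c3_const: float = 0.5
    c4_mode: str = "const"          # const | half_min_type3
    c4_const: float = 0.25
    double_type1: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.thr1 <= 1 and 0 < self.thr2 <= 1):
            raise ValueError("thr1 and thr2 must lie in (0, 1]")
        if self.c1 < 1:
            raise ValueError("c1 must be >= 1")
        if self.c3_mode not in ("const", "min_type4", "half_min_type4"):
            raise ValueError(f"unknown c3_mode {self.c3_mode!r}")
        if self.c4_mode not in ("const", "half_min_type3"):
            raise ValueError(f"unknown c4_mode {self.c4_mode!r}")


#: The five subfamily scenarios.  thr1=0.98 reflects the exceptional
#: conservation of CaSR; for CaSR both lower caps are chained to the
#: preceding type's minimum weight instead of a fixed constant.
PRESETS: dict[str, WeightConstants] = {
    "CaSR": WeightConstants(thr1=0.98, thr2=0.8, c1=1.0,
                            c3_mode="half_min_type4", c4_mode="half_min_type3"),
    "GPRC6A": WeightConstants(thr1=0.8, thr2=0.8, c1=1.0,
                              c3_mode="min_type4", c4_mode="const",
                              c4_const=0.2, double_type1=True),
    "TAS1R1": WeightConstants(thr1=0.8, thr2=0.8, c1=1.0,
                              c3_mode="const", c3_const=0.5,
                              c4_mode="const", c4_const=0.25),
    "TAS1R2": WeightConstants(thr1=0.8, thr2=0.8, c1=1.5,
                              c3_mode="const", c3_const=0.5,
                              c4_mode="const", c4_const=0.2),
    "TAS1R3": WeightConstants(thr1=0.8, thr2=0.8, c1=1.0,
                              c3_mode="const", c3_const=0.5,
                              c4_mode="const", c4_const=0.25),
}


# ---------------------------------------------------------------------------
# Column frequencies and representatives (Step 1)
# ---------------------------------------------------------------------------

def column_frequencies(aln: Alignment) -> np.ndarray:
    """Observed per-column frequency vectors over the 21 symbols (20 aa + gap).

    Gaps are first-class symbols: they appear in the denominator and may be
    the most frequent symbol of a column.
    """
    if not aln.sequences or aln.n_columns == 0:
        raise ValueError("cannot compute frequencies of an empty alignment")
    n_rows = len(aln.sequences)
    counts = np.zeros((aln.n_columns, len(SYMBOLS)))
    for seq in aln.sequences.values():
        idx = np.fromiter((SYMBOL_INDEX[c] for c in seq), int, count=len(seq))
        np.add.at(counts, (np.arange(aln.n_columns), idx), 1.0)
    return counts / n_rows


def top_symbol(freq_row: np.ndarray) -> tuple[str, float]:
    """Most frequent symbol of one column; residues beat gap on ties and
    residues tie-break alphabetically (first argmax over the symbol order)."""
    i = int(np.argmax(freq_row))
    return SYMBOLS[i], float(freq_row[i])


@dataclass(frozen=True)
class PositionRepresentatives:
    """Per-column representatives and scores for the three groups."""

    r_t: np.ndarray  # object arrays of single-character symbols
    s_t: np.ndarray
    r_c: np.ndarray
    s_c: np.ndarray
    r_r: np.ndarray
    s_r: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.r_t)


def _group_representative(
    tops: list[tuple[str, float]], r_t: str
) -> tuple[str, float]:
    """Representative of a (closest or rest) group at one column.

    Single subfamily: its top symbol and frequency.  Several subfamilies:
    if any member's top symbol equals the target representative, that symbol
    wins with the (largest) matching member frequency; otherwise the member
    with the highest top frequency provides the symbol and the score is the
    mean of all member top frequencies.
    """
    if len(tops) == 1:
        return tops[0]
    matching = [f for a, f in tops if a == r_t]
    if matching:
        return r_t, max(matching)
    best_symbol = max(tops, key=lambda t: t[1])[0]
    return best_symbol, sum(f for _, f in tops) / len(tops)


def select_representatives(
    freqs: dict[str, np.ndarray], scheme: GroupingScheme
) -> PositionRepresentatives:
    """Choose per-column representative symbols and scores for each group.

    ``freqs`` maps subfamily id to its ``(L, 21)`` column frequency matrix;
    all matrices must share the column axis (same reference coordinates).
    A multi-subfamily *target* group is pooled by averaging frequency
    vectors before taking the top symbol.
    """
    for g in (scheme.target, scheme.closest, scheme.rest):
        for s in g:
            if s not in freqs:
                raise KeyError(f"no frequencies for subfamily {s!r}")
    n_cols = {freqs[s].shape[0] for g in (scheme.target, scheme.closest, scheme.rest) for s in g}
    if len(n_cols) != 1:
        raise ValueError("subfamily frequency matrices have differing column counts")
    L = n_cols.pop()

    target_freq = np.mean([freqs[s] for s in scheme.target], axis=0)
    out = {k: np.empty(L, object) for k in ("r_t", "r_c", "r_r")}
    scores = {k: np.empty(L) for k in ("s_t", "s_c", "s_r")}
    for k in range(L):
        r_t, s_t = top_symbol(target_freq[k])
        out["r_t"][k], scores["s_t"][k] = r_t, s_t
        for key, group in (("c", scheme.closest), ("r", scheme.rest)):
            tops = [top_symbol(freqs[s][k]) for s in group]
            r, s = _group_representative(tops, r_t)
            out[f"r_{key}"][k], scores[f"s_{key}"][k] = r, s
    return PositionRepresentatives(
        out["r_t"], scores["s_t"], out["r_c"], scores["s_c"], out["r_r"], scores["s_r"]
    )


# ---------------------------------------------------------------------------
# Normalized BLOSUM
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def normalized_blosum(a: str, b: str) -> float:
    """BLOSUM62 log-odds of ``(a, b)`` divided by the maximum of row ``a``
    (over the 20 canonical residues).  Equals 1 when ``b`` maximizes the row
    (the diagonal, for every canonical residue)."""
    if a not in AA_INDEX or b not in AA_INDEX:
        raise ValueError(f"normalized_blosum expects canonical residues, got {a!r},{b!r}")
    row_max = max(_BLOSUM62[a][x] for x in AMINO_ACIDS)
    return float(_BLOSUM62[a][b] / row_max)


# ---------------------------------------------------------------------------
# Position typing (Step 2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionTyping:
    category: np.ndarray   # int, 1..6
    ptype: np.ndarray      # object, one of "I","II","III","IV"
    score: np.ndarray      # float > 0


def _type_one_position(
    r_t: str, s_t: float, r_c: str, s_c: float, r_r: str, s_r: float,
    consts: WeightConstants,
) -> tuple[int, str, float]:
    """Six-category decision tree for one column; returns (category, type, score)."""
    total = s_t + s_c + s_r

    def _score(ptype: str) -> float:
        return 1.0 / total if ptype == TYPE_II else total

    if r_c == r_r == GAP:                                   # category 1
        ptype = TYPE_II if r_t == GAP else TYPE_I
        return 1, ptype, _score(ptype)
    if r_t == GAP:                                          # category 2
        ptype = TYPE_II if (r_c == GAP or r_r == GAP) else TYPE_I
        return 2, ptype, _score(ptype)
    if r_t != r_c and r_c != r_r and r_t != r_r:            # category 3
        if r_c != GAP and r_r != GAP:
            if s_t >= consts.thr1 and s_c >= consts.thr2 and s_r >= consts.thr2:
                ptype = TYPE_I
            elif (normalized_blosum(r_t, r_c) <= consts.thr_bls
                  and normalized_blosum(r_t, r_r) <= consts.thr_bls):
                ptype = TYPE_I
            else:
                ptype = TYPE_IV
        elif r_c == GAP:
            if s_t >= consts.thr1 and s_r >= consts.thr2:
                ptype = TYPE_I
            elif normalized_blosum(r_t, r_r) <= consts.thr_bls:
                ptype = TYPE_I
            else:
                ptype = TYPE_IV
        else:  # r_r == GAP
            if s_t >= consts.thr1 and s_c >= consts.thr2:
                ptype = TYPE_I
            elif normalized_blosum(r_t, r_c) <= consts.thr_bls:
                ptype = TYPE_I
            else:
                ptype = TYPE_IV
        return 3, ptype, _score(ptype)
    if r_t == r_c:                                          # category 4
        return 4, TYPE_II, _score(TYPE_II)
    if r_t == r_r:                                          # category 5 (r_t != r_c)
        if r_c == GAP:
            ptype = TYPE_III
        elif normalized_blosum(r_t, r_c) <= consts.thr_bls and s_c >= consts.thr2:
            ptype = TYPE_III
        else:
            ptype = TYPE_II
        return 5, ptype, _score(ptype)
    # r_c == r_r != r_t, non-gap (gap pair handled by category 1)  category 6
    if s_t >= consts.thr1 and s_c >= consts.thr2 and s_r >= consts.thr2:
        ptype = TYPE_I
    elif normalized_blosum(r_t, r_c) <= consts.thr_bls:
        ptype = TYPE_I
    else:
        ptype = TYPE_II
    return 6, ptype, _score(ptype)


def assign_position_type(
    reps: PositionRepresentatives, consts: WeightConstants
) -> PositionTyping:
    """Assign category, type and initial score to every column."""
    L = reps.n_columns
    category = np.zeros(L, int)
    ptype = np.empty(L, object)
    score = np.zeros(L)
    for k in range(L):
        category[k], ptype[k], score[k] = _type_one_position(
            reps.r_t[k], reps.s_t[k], reps.r_c[k], reps.s_c[k],
            reps.r_r[k], reps.s_r[k], consts,
        )
    return PositionTyping(category, ptype, score)


# ---------------------------------------------------------------------------
# Final weights (Algorithm 2)
# ---------------------------------------------------------------------------

def compute_position_weights(
    typing: PositionTyping, consts: WeightConstants
) -> np.ndarray:
    """Final per-column weights.

    Type I weights scale initial scores by their minimum times ``c1``; the
    type IV cap ``c2`` is the mean type-I weight; the type III cap ``c3`` and
    type II cap ``c4`` follow the preset policy (fixed constant, minimum of
    the preceding type, or half of it).  Within each type the weight grows
    linearly with the initial score.  Requires at least one type I column
    (``c2`` is undefined otherwise).
    """
    t = typing.ptype
    s = typing.score
    weights = np.zeros(len(s))

    i_mask = t == TYPE_I
    if not i_mask.any():
        raise ValueError("no type I positions: c2 (type IV cap) is undefined")
    weights[i_mask] = s[i_mask] / s[i_mask].min() * consts.c1
    c2 = float(weights[i_mask].mean())

    iv_mask = t == TYPE_IV
    if iv_mask.any():
        weights[iv_mask] = s[iv_mask] / s[iv_mask].max() * c2
        min_iv = float(weights[iv_mask].min())
    else:
        min_iv = None

    if consts.c3_mode == "const":
        c3 = consts.c3_const
    elif min_iv is None:
        logger.warning("no type IV positions; c3 falls back to 0.5")
        c3 = 0.5
    elif consts.c3_mode == "min_type4":
        c3 = min_iv
    else:  # half_min_type4
        c3 = min_iv / 2.0

    iii_mask = t == TYPE_III
    if iii_mask.any():
        weights[iii_mask] = s[iii_mask] / s[iii_mask].max() * c3
        min_iii = float(weights[iii_mask].min())
    else:
        min_iii = None

    if consts.c4_mode == "const":
        c4 = consts.c4_const
    elif min_iii is None:
        logger.warning("no type III positions; c4 falls back to 0.2")
        c4 = 0.2
    else:  # half_min_type3
        c4 = min_iii / 2.0

    ii_mask = t == TYPE_II
    if ii_mask.any():
        weights[ii_mask] = s[ii_mask] / s[ii_mask].max() * c4

    if consts.double_type1:
        weights[i_mask] *= 2.0
    return weights


# ---------------------------------------------------------------------------
# Weighted profile
# ---------------------------------------------------------------------------

#: Uniform amino-acid background for log-odds scoring.
BACKGROUND = np.full(20, 1.0 / 20.0)

#: Floor applied to match emissions before log-odds, so symbols unseen in the
#: training alignment stay finitely (strongly) penalized.
EMISSION_FLOOR = 1e-4

# transition penalties in bits for the global profile aligner; stiff enough
# that skipping profile columns cannot rescue a mismatching sequence
_GAP_OPEN = -15.0
_GAP_EXTEND = -3.0


@dataclass(frozen=True)
class WeightedProfile:
    """Per-column emissions and weights of a subfamily profile.

    ``baseline`` rows are observed residue frequencies of the gap-removed
    target alignment, renormalized over the 20 residues and floored;
    ``reweighted`` rows are the baseline raised to the column weight and
    renormalized (the export form of the weighting; scoring applies the
    weight to the log-odds contribution directly, which is the same identity
    at weight 1).
    """

    name: str
    baseline: np.ndarray        # (L, 20)
    weights: np.ndarray         # (L,)
    column_map: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.baseline.shape != (len(self.weights), 20):
            raise ValueError("baseline emissions and weights disagree in length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    @property
    def n_columns(self) -> int:
        return len(self.weights)

    @property
    def reweighted(self) -> np.ndarray:
        powered = np.power(self.baseline, self.weights[:, None])
        return powered / powered.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.baseline.argmax(axis=1))

    @property
    def match_log_odds(self) -> np.ndarray:
        """(L, 20) weighted match log-odds in bits."""
        return self.weights[:, None] * np.log2(self.baseline / BACKGROUND)


def baseline_emissions(aln: Alignment) -> np.ndarray:
    """Observed residue frequencies per column, gap mass removed, floored."""
    freqs = column_frequencies(aln)[:, :20]
    sums = freqs.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("all-gap column in alignment; remove reference-gap columns first")
    em = freqs / sums
    em = np.maximum(em, EMISSION_FLOOR)
    return em / em.sum(axis=1, keepdims=True)


def build_weighted_profile(
    aln: Alignment, weights: np.ndarray, name: str = "profile"
) -> WeightedProfile:
    w = np.asarray(weights, float)
    if len(w) != aln.n_columns:
        raise ValueError("one weight per column required")
    return WeightedProfile(name, baseline_emissions(aln), w, aln.column_map)


def score_sequence(profile: WeightedProfile, sequence: str) -> float:
    """Best-path weighted log-odds (bits) of a sequence against the profile.

    Global affine-gap dynamic programming over match/insert/delete states:
    insertions emit at background (log-odds 0) and gaps pay open/extend
    penalties, so the score is dominated by the weighted match log-odds.
    """
    seq = sequence.replace(GAP, "").upper()
    if not seq:
        raise ValueError("cannot score an empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"sequence contains non-residue symbols: {sorted(bad)}")
    m = profile.match_log_odds  # (L, 20)
    L = profile.n_columns
    n = len(seq)
    sidx = np.fromiter((AA_INDEX[c] for c in seq), int, count=n)

    neg = -np.inf
    # rows indexed by sequence position 0..n; vectors over profile columns 0..L
    M = np.full(L + 1, neg)
    I = np.full(L + 1, neg)
    D = np.full(L + 1, neg)
    M[0] = 0.0
    # deletions along the first row (profile columns skipped before any residue)
    for k in range(1, L + 1):
        D[k] = max(M[k - 1] + _GAP_OPEN, D[k - 1] + _GAP_EXTEND)
    for i in range(1, n + 1):
        Mp, Ip, Dp = M, I, D
        M = np.full(L + 1, neg)
        I = np.full(L + 1, neg)
        D = np.full(L + 1, neg)
        best_prev = np.maximum(np.maximum(Mp, Ip), Dp)
        I[:] = np.maximum(np.maximum(Mp + _GAP_OPEN, Ip + _GAP_EXTEND),
                          Dp + _GAP_OPEN)
        emit = m[:, sidx[i - 1]]
        M[1:] = best_prev[:-1] + emit
        for k in range(1, L + 1):
            D[k] = max(max(M[k - 1], I[k - 1]) + _GAP_OPEN, D[k - 1] + _GAP_EXTEND)
    return float(max(M[L], I[L], D[L]))


def classify_sequences(
    profiles: dict[str, WeightedProfile], sequences: dict[str, str],
    hit_threshold: float = 0.0,
) -> dict[str, str | None]:
    """Assign each sequence to the best-scoring profile, or ``None``.

    A sequence is assigned to the argmax profile provided that score exceeds
    ``hit_threshold`` (bits); otherwise it is unassigned.
    """
    out: dict[str, str | None] = {}
    for sid, seq in sequences.items():
        scores = {name: score_sequence(p, seq) for name, p in profiles.items()}
        best = max(scores, key=scores.get)  # type: ignore[arg-type]
        out[sid] = best if scores[best] > hit_threshold else None
    return out


# ---------------------------------------------------------------------------
# End-to-end profile construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileBuildResult:
    profile: WeightedProfile
    representatives: PositionRepresentatives
    typing: PositionTyping
    weights: np.ndarray


def merge_alignments(alns: list[Alignment]) -> Alignment:
    """Stack rows of alignments sharing the same column coordinates."""
    maps = {a.column_map for a in alns}
    if len(maps) != 1:
        raise ValueError("alignments do not share column coordinates")
    rows: dict[str, str] = {}
    for a in alns:
        for sid, seq in a.sequences.items():
            if sid in rows:
                raise ValueError(f"duplicate sequence id {sid!r}")
            rows[sid] = seq
    return Alignment(rows, alns[0].reference_id, alns[0].column_map)


def build_subfamily_profile(
    alignments: dict[str, Alignment],
    scheme: GroupingScheme,
    consts: WeightConstants,
    name: str = "profile",
) -> ProfileBuildResult:
    """Full pipeline for one target subfamily.

    All subfamily alignments must share column coordinates (they come from
    one superfamily MSA).  Columns that are gaps in the target's reference
    row are removed; representatives, types and weights are computed on the
    surviving columns; emissions come from the (merged) target rows.
    """
    from .io_core import remove_reference_gap_columns

    target_aln = merge_alignments([alignments[s] for s in scheme.target])
    target_aln = remove_reference_gap_columns(target_aln)
    kept = [list(alignments[next(iter(scheme.target))].column_map).index(c)
            for c in target_aln.column_map]

    freqs = {}
    for group in (scheme.target, scheme.closest, scheme.rest):
        for s in group:
            freqs[s] = column_frequencies(alignments[s])[kept]
    reps = select_representatives(freqs, scheme)
    typing = assign_position_type(reps, consts)
    weights = compute_position_weights(typing, consts)
    profile = build_weighted_profile(target_aln, weights, name)
    return ProfileBuildResult(profile, reps, typing, weights)


# ---------------------------------------------------------------------------
# Subfamily assignment rule
# ---------------------------------------------------------------------------

def assign_subfamily(
    hits: dict[str, tuple[float, float]],
    taxon: str,
    taxonomic_ranges: dict[str, set[str]],
) -> str | None:
    """Three-condition subfamily assignment.

    ``hits`` maps subfamily id to ``(score, e_value)`` of its profile hit.
    A sequence is assigned to subfamily *s* iff the maximum score and the
    minimum e-value both belong to *s* and the taxon lies within *s*'s
    most-common-highest-taxonomic-level clade; otherwise it is unassigned.
    """
    if not hits:
        raise ValueError("at least one profile hit is required")
    best_score = max(hits, key=lambda s: hits[s][0])
    best_evalue = min(hits, key=lambda s: hits[s][1])
    if best_score != best_evalue:
        return None
    if taxon not in taxonomic_ranges.get(best_score, set()):
        return None
    return best_score


# ---------------------------------------------------------------------------
# HMMER3 export
# ---------------------------------------------------------------------------

def export_hmmer3(profile: WeightedProfile, path) -> None:
    """Write the reweighted profile as a HMMER3 ASCII file via pyhmmer.

    Match emissions are the weight-powered, renormalized column
    distributions; insert emissions are background and transitions are fixed
    documented defaults (the weighting only alters emissions).
    """
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    M = profile.n_columns
    hmm = pyhmmer.plan7.HMM(alphabet, M, profile.name)
    em = np.asarray(hmm.match_emissions)
    em[1:, :] = profile.reweighted
    ins = np.asarray(hmm.insert_emissions)
    ins[:, :] = BACKGROUND
    tr = np.asarray(hmm.transition_probabilities)
    # columns: MM MI MD IM II DM DD
    tr[:, :] = [0.9, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5]
    tr[0, :] = [0.95, 0.05, 0.0, 0.5, 0.5, 1.0, 0.0]
    tr[M, :] = [0.95, 0.05, 0.0, 0.5, 0.5, 1.0, 0.0]
    hmm.validate()
    with open(path, "wb") as fh:
        hmm.write(fh, binary=False)


def write_weight_table(
    typing: PositionTyping, weights: np.ndarray, column_map: tuple[int, ...], path
) -> None:
    """TSV of (column, reference_position, category, type, initial_score, weight)."""
    import pandas as pd

    pd.DataFrame({
        "column": np.arange(len(weights)),
        "reference_position": np.arange(1, len(weights) + 1),
        "original_column": list(column_map),
        "category": typing.category,
        "type": typing.ptype,
        "initial_score": typing.score,
        "weight": weights,
    }).to_csv(path, sep="\t", index=False)
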