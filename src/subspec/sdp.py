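"""Specificity-determining-position (SDP) scoring.

Each subfamily contributes, per reference position, an *acceptability
distribution* over the 20 amino acids derived from its phylogenetic tree and
ancestral-reconstruction posteriors: starting from the root posterior, every
independent gain of an amino acid along the tree (a positive parent-to-child
posterior difference at an internal node) adds mass once, regardless of how
many descendants inherit it.  No distance weighting is applied.  The raw
mass is normalized to the simplex.

The SDP score of a position then contrasts the target subfamily's
representative amino acid (its acceptability mode) against every other
subfamily: a subfamily that conserves the same amino acid pulls the score
down, a subfamily that is free to vary — or conserves a different amino
acid — pushes it up, with contributions discounted by the branch-length
distance between subfamily root nodes.  Positions scoring above 5 are
flagged as subfamily-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX
from .io_core import AncestralReconstruction

SDP_SPECIFIC_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# adjPHACT acceptability distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubfamilyDistribution:
    """Per-position acceptability distributions of one subfamily.

    ``matrix`` has shape ``(n_positions, 20)``; each row sums to 1 and its
    positions are 1-based reference coordinates (reference-gap columns are
    removed upstream and never scored).
    """

    subfamily_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.matrix < -1e-12) or np.any(
            np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("acceptability rows must be probability vectors")

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    def representative(self, position: int) -> tuple[str, float]:
        """Modal amino acid and its acceptability at a 1-based position."""
        row = self.matrix[position - 1]
        i = int(np.argmax(row))
        return AMINO_ACIDS[i], float(row[i])


def adjphact_distribution(
    tree: dendropy.Tree, asr: AncestralReconstruction, column: int
) -> np.ndarray:
    """Acceptability vector over 20 amino acids for one 0-based column.

    raw(a) = P_root(a) + sum over non-root internal nodes n of
    max(0, P_n(a) - P_parent(n)(a)), normalized to sum 1.  Leaves are
    excluded: ancestral reconstruction posteriors exist for internal nodes
    only, and leaf states already shaped those posteriors.
    """
    root = tree.seed_node
    raw = asr.vector(root.label, column).astype(float).copy()
    for node in tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        p_node = asr.vector(node.label, column)
        p_parent = asr.vector(node.parent_node.label, column)
        raw += np.maximum(0.0, p_node - p_parent)
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"zero acceptability mass at column {column}")
    return raw / total


def adjphact_all_positions(
    tree: dendropy.Tree, asr: AncestralReconstruction, subfamily_id: str
) -> SubfamilyDistribution:
    mat = np.vstack([
        adjphact_distribution(tree, asr, k) for k in range(asr.n_columns)
    ])
    return SubfamilyDistribution(subfamily_id, mat)


# ---------------------------------------------------------------------------
# Root-to-root distances
# ---------------------------------------------------------------------------

def subfamily_root_distance(
    supertree: dendropy.Tree, target_taxa, other_taxa
) -> float:
    """Branch-length path distance between two clade root (MRCA) nodes."""
    mrca_a = supertree.mrca(taxon_labels=list(target_taxa))
    mrca_b = supertree.mrca(taxon_labels=list(other_taxa))
    if mrca_a is None or mrca_b is None:
        raise ValueError("clade not found in supertree")
    if mrca_a is mrca_b:
        raise ValueError("clades share the same root node (distance would be 0)")

    def path_to_root(node):
        path = [node]
        while node.parent_node is not None:
            node = node.parent_node
            path.append(node)
        return path

    pa = path_to_root(mrca_a)
    pb = {id(n): i for i, n in enumerate(path_to_root(mrca_b))}
    dist = 0.0
    for node in pa:
        if id(node) in pb:
            # node is the common ancestor; add the b-side path up to it
            b = mrca_b
            for _ in range(pb[id(node)]):
                dist += b.edge.length or 0.0
                b = b.parent_node
            break
        dist += node.edge.length or 0.0
    if dist <= 0:
        raise ValueError("root-to-root distance must be > 0")
    return dist


# ---------------------------------------------------------------------------
# SDP score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SdpInputs:
    """Inputs of the per-position SDP score.

    ``a_t`` / ``p_t`` — target representative amino acid and its target
    acceptability; ``others`` — for each non-target subfamily a tuple
    ``(a_i, p_i_ai, p_i_at, d_i)``: its own representative and acceptability,
    the acceptability of the *target's* representative in that subfamily, and
    the root-to-root distance to the target.
    """

    a_t: str
    p_t: float
    others: tuple[tuple[str, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.others:
            raise ValueError("at least one non-target subfamily is required")
        for a_i, p_i_ai, p_i_at, d_i in self.others:
            if d_i <= 0:
                raise ValueError("root-to-root distance d_i must be > 0")
            for p in (p_i_ai, p_i_at):
                if not 0.0 <= p <= 1.0 + 1e-12:
                    raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.p_t <= 1.0 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")


def sdp_score(inputs: SdpInputs) -> float:
    """SDP score of one position.

    For each other subfamily i: cons_i = +1 if P_i(a_i) > 0.5 else -1;
    S_i = -exp(P_i(a_T)) when the subfamily conserves the target's residue
    (cons_i = +1 and a_i = a_T), else S_i = exp(1) - exp(P_i(a_i)).  The
    overall weight is w = 1 - max_i P_i(a_T), and

        SDP = (exp(P_T(a_T)) + w * sum_i S_i / D_i) * P_T(a_T).
    """
    total = 0.0
    max_p_at = 0.0
    for a_i, p_i_ai, p_i_at, d_i in inputs.others:
        cons = 1 if p_i_ai > 0.5 else -1
        if cons == 1 and a_i == inputs.a_t:
            s_i = -math.exp(p_i_at)
        else:  # (cons == -1 and a_i == a_t) or a_i != a_t
            s_i = math.exp(1.0) - math.exp(p_i_ai)
        total += s_i / d_i
        max_p_at = max(max_p_at, p_i_at)
    omega = 1.0 - max_p_at
    return (math.exp(inputs.p_t) + omega * total) * inputs.p_t


def sdp_table(
    target: SubfamilyDistribution,
    others: dict[str, SubfamilyDistribution],
    distances: dict[str, float],
    threshold: float = SDP_SPECIFIC_THRESHOLD,
) -> pd.DataFrame:
    """Per-position SDP scores for a target subfamily.

    All distributions must share the target's reference coordinates (one row
    per reference position).  Returns a DataFrame with columns
    ``reference_position``, ``a_t``, ``sdp`` and ``specific`` (SDP > 5).
    """
    if set(others) != set(distances):
        raise ValueError("distances must be given for exactly the other subfamilies")
    for name, dist in others.items():
        if dist.n_positions != target.n_positions:
            raise ValueError(
                f"subfamily {name} has {dist.n_positions} positions, "
                f"target has {target.n_positions}"
            )
    rows = []
    for pos in range(1, target.n_positions + 1):
        a_t, p_t = target.representative(pos)
        others_inputs = []
        for name, dist in others.items():
            a_i, p_i_ai = dist.representative(pos)
            p_i_at = float(dist.matrix[pos - 1, AA_INDEX[a_t]])
            others_inputs.append((a_i, p_i_ai, p_i_at, distances[name]))
        score = sdp_score(SdpInputs(a_t, p_t, tuple(others_inputs)))
        rows.append((pos, a_t, score, score > threshold))
    return pd.DataFrame(rows, columns=["reference_position", "a_t", "sdp", "specific"])


def write_attribute_file(table: pd.DataFrame, path, attribute: str = "sdpScore") -> None:
    """Structure-viewer attribute file (position -> score) for coloring."""
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\nmatch mode: 1-to-1\nrecipient: residues\n")
        for _, row in table.iterrows():
            fh.write(f"\t:{int(row.reference_position)}\t{row.sdp:.6f}\n")
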