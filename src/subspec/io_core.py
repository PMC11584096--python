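"""Readers, containers and small shared statistics.

Covers the four domain containers used throughout the package:

* :class:`Alignment` — an aligned FASTA block with a designated reference
  (query-species) row and a ``column_map`` that records, for every retained
  column, its index in the original alignment.  All downstream outputs report
  1-based reference coordinates through this map.
* trees — rooted :class:`dendropy.Tree` objects whose unlabeled internal
  nodes receive deterministic preorder ids (``N0``, ``N1`` ...) so ancestral
  state tables are joinable.
* :class:`AncestralReconstruction` — per internal node, per column posterior
  probability vectors over the 20 amino acids.
* :class:`Structure` — heavy-atom coordinates of a protein structure with an
  active/inactive state label.

Plus Welch's unequal-variance t test, the statistic used both for the
branch-length conservation comparison and for contact-change testing.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .alphabet import AMINO_ACIDS, GAP, sanitize_sequence

logger = logging.getLogger(__name__)

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment with a designated reference row.

    ``column_map[i]`` is the index of retained column ``i`` in the original
    alignment; a freshly read alignment has the identity map.  1-based
    reference positions refer to the residues of the (gap-free) reference row
    after :func:`remove_reference_gap_columns`.
    """

    sequences: dict[str, str]
    reference_id: str
    column_map: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")
        lengths = {sid: len(s) for sid, s in self.sequences.items()}
        ref_len = lengths[self.reference_id]
        for sid, n in lengths.items():
            if n != ref_len:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {n}, expected {ref_len}"
                )
        if self.column_map is None:
            object.__setattr__(self, "column_map", tuple(range(ref_len)))
        if len(self.column_map) != ref_len:
            raise ValueError("column_map length does not match alignment width")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("column_map must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.column_map)

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def reference_sequence(self) -> str:
        return self.sequences[self.reference_id]

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.sequences.values())

    def subset(self, ids: list[str]) -> "Alignment":
        missing = [i for i in ids if i not in self.sequences]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        ref = self.reference_id if self.reference_id in ids else ids[0]
        return Alignment({i: self.sequences[i] for i in ids}, ref, self.column_map)

    def reference_position(self, column_index: int) -> int:
        """1-based reference coordinate of retained column ``column_index``.

        Only meaningful after reference-gap removal (reference row gap-free).
        """
        return column_index + 1


def read_alignment(path, reference_id: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs: dict[str, str] = {}
    for rec in records:
        seqs[rec.id] = sanitize_sequence(str(rec.seq), seq_id=rec.id)
    return Alignment(seqs, reference_id)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def remove_reference_gap_columns(aln: Alignment) -> Alignment:
    """Drop every column where the reference row carries a gap.

    Idempotent; the surviving original column indices are recorded in
    ``column_map`` so downstream scores can be reported in reference
    coordinates.
    """
    ref = aln.sequences[aln.reference_id]
    keep = [i for i, c in enumerate(ref) if c != GAP]
    if not keep:
        logger.warning("reference row is all gaps; resulting alignment is empty")
    new_map = tuple(aln.column_map[i] for i in keep)
    new_seqs = {
        sid: "".join(seq[i] for i in keep) for sid, seq in aln.sequences.items()
    }
    return Alignment(new_seqs, aln.reference_id, new_map)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign deterministic preorder ids ``N0, N1, ...`` to unlabeled internals."""
    idx = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None or node.label == "" or _is_support_value(node.label):
            node.label = f"N{idx}"
        idx += 1


def _is_support_value(label: str) -> bool:
    try:
        float(label)
    except (TypeError, ValueError):
        return False
    return True


def read_tree(path=None, *, data: str | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Unlabeled internal nodes (or internal labels that are bare numbers, i.e.
    support values) get deterministic preorder ids.  Missing branch lengths
    are treated as 0 with a warning.  A trifurcating root is rejected: root
    the tree on an outgroup first.
    """
    if data is None:
        with open(path) as fh:
            data = fh.read()
    if not data.strip():
        raise ValueError("empty Newick input")
    tree = dendropy.Tree.get(
        data=data, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    tree.is_rooted = True
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        raise ValueError(
            "tree root is multifurcating (unrooted tree?); root it on an "
            "outgroup before use"
        )
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = edge.length or 0.0
            continue
        if edge.length is None:
            n_missing += 1
            edge.length = 0.0
        elif edge.length < 0:
            raise ValueError("negative branch length")
    if n_missing:
        logger.warning("%d branch(es) had no length; treated as 0", n_missing)
    # move taxon labels of internal nodes into node labels for uniform access
    # (and drop the internal taxa so round-tripped newick stays clean)
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            if node.label is None and node.taxon is not None:
                node.label = node.taxon.label
            node.taxon = None
    _label_internal_nodes(tree)
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def internal_labels(tree: dendropy.Tree) -> list[str]:
    return [n.label for n in tree.preorder_node_iter() if not n.is_leaf()]


def root_to_leaf_distance(tree: dendropy.Tree, leaf_label: str) -> float:
    """Sum of branch lengths on the root-to-leaf path."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == leaf_label:
            dist = 0.0
            node = leaf
            while node.parent_node is not None:
                dist += node.edge.length or 0.0
                node = node.parent_node
            return dist
    raise KeyError(f"leaf {leaf_label!r} not in tree")


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralReconstruction:
    """Per internal node, per column posterior vectors over 20 amino acids.

    ``probabilities[node_id]`` has shape ``(n_columns, 20)`` with rows on the
    probability simplex; columns follow :data:`subspec.alphabet.AMINO_ACIDS`.
    """

    probabilities: dict[str, np.ndarray]
    n_columns: int

    def vector(self, node_id: str, column: int) -> np.ndarray:
        try:
            return self.probabilities[node_id][column]
        except KeyError:
            raise KeyError(f"no ancestral probabilities for node {node_id!r}")


def read_ancestral_states(path, tree: dendropy.Tree) -> AncestralReconstruction:
    """Read a tab-separated ancestral state table.

    Layout (as produced by ML ancestral reconstruction tools): columns
    ``node_id``, ``column`` (1-based site index) and 20 probability columns
    ``p_A`` ... ``p_Y`` in alphabetical residue order.  Vectors whose sum is
    within 1e-3 of 1 are renormalized; larger deviations are an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["node_id", "column"] + [f"p_{a}" for a in AMINO_ACIDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ancestral state table missing columns: {missing}")
    known = set(internal_labels(tree))
    bad = set(df["node_id"].astype(str)) - known
    if bad:
        raise ValueError(f"ancestral table refers to unknown node id(s): {sorted(bad)}")
    n_columns = int(df["column"].max())
    probs: dict[str, np.ndarray] = {}
    prob_cols = [f"p_{a}" for a in AMINO_ACIDS]
    for node_id, grp in df.groupby("node_id", sort=False):
        mat = np.zeros((n_columns, 20))
        vecs = grp[prob_cols].to_numpy(float)
        sums = vecs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"node {node_id}: probability vector sum deviates from 1 by {worst:.4g}"
            )
        mat[grp["column"].to_numpy(int) - 1] = vecs / sums[:, None]
        probs[str(node_id)] = mat
    return AncestralReconstruction(probs, n_columns)


def write_ancestral_states(asr: AncestralReconstruction, path) -> None:
    rows = []
    for node_id, mat in asr.probabilities.items():
        for col in range(mat.shape[0]):
            rows.append([node_id, col + 1, *mat[col]])
    df = pd.DataFrame(rows, columns=["node_id", "column"] + [f"p_{a}" for a in AMINO_ACIDS])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    chain: str
    resseq: int
    resname: str
    name: str
    x: float
    y: float
    z: float

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAIN_CHAIN_ATOMS


@dataclass
class Structure:
    """Heavy atoms of one structure with an activation-state label."""

    structure_id: str
    state: str  # "active" | "inactive"
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.state not in ("active", "inactive"):
            raise ValueError(f"state must be 'active' or 'inactive', got {self.state!r}")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain, a.resseq, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {self.structure_id}")
            seen.add(key)
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates for atom {key}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body transformed copy (used for invariance checks)."""
        xyz = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(self.structure_id, self.state, atoms)


def read_structure(path, state: str, structure_id: str | None = None) -> Structure:
    """Read heavy atoms from a PDB or mmCIF file via gemmi.

    Hydrogens and waters are dropped; for altloc'd atoms only the
    highest-occupancy conformer is kept.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    st.remove_waters()
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.name == "H":
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                atoms.append(
                    Atom(chain.name, residue.seqid.num, residue.name, name,
                         atom.pos.x, atom.pos.y, atom.pos.z)
                )
    return Structure(structure_id or st.name or str(path), state, atoms)


def write_structure_pdb(structure: Structure, path) -> None:
    """Write a structure as a minimal PDB file (heavy atoms only)."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in structure.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        key = (a.chain, a.resseq)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resseq, " ")
            chains[a.chain].add_residue(res)
            residues[key] = chains[a.chain][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.name[0])
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        atom.occ = 1.0
        residues[key].add_atom(atom)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Shared statistics
# ---------------------------------------------------------------------------

def welch_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t test.

    Degenerate inputs — fewer than two observations on a side, or zero
    pooled variance (including identical samples) — return ``(0.0, 1.0)``
    with a warning rather than failing, so bulk screens over many unit pairs
    never abort on a constant pair.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        logger.warning("welch_t_test: need >= 2 observations per sample; p set to 1")
        return 0.0, 1.0
    # tolerance absorbs rounding noise of numerically identical samples
    scale = max(1.0, np.abs(a).max(initial=0.0), np.abs(b).max(initial=0.0))
    if a.var(ddof=1) + b.var(ddof=1) <= (1e-12 * scale) ** 2:
        logger.warning("welch_t_test: zero variance in both samples; p set to 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
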