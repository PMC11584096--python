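"""Deterministic synthetic fixtures with planted signal.

Three generators emulate the statistical structure each analysis stage
assumes, so every stage can be exercised offline:

* :func:`generate_subfamily_msas` — a superfamily of subfamily clades with
  per-column evolutionary *plans* (target-specific, globally conserved,
  shared with the closest clade, freely variable, or gap blocks).  Columns
  are simulated by planting substitutions down a generated tree (per-branch
  substitution probability grows with branch length), not drawn i.i.d., so
  the independent-event counting of the acceptability traversal is genuinely
  exercised.  The generator also emits per-subfamily trees, ancestral state
  tables consistent with the simulated history, held-out sequences, and a
  truth table.
* :func:`generate_structure_ensembles` — active/inactive ensembles of toy
  poly-alanine-like structures (backbone + CB/CG pseudo side chain) whose
  only systematic difference is a list of planted contact changes, under
  Gaussian coordinate jitter.  Side-chain geometry guarantees at least one
  atom pair of each planted contact sits in the linear zone of the contact
  kernel, so jitter produces the score variance the Welch screen needs.
* :func:`generate_mutation_dataset` — GoF/LoF mutation tables drawn from the
  planted column classes (GoF: substitution tolerated in non-target
  subfamilies at a target-specific column; LoF: substitution unseen anywhere
  at a globally conserved column), with label noise.

Every generator is a pure function of its seed.  The packaged 22-mutation
literature validation table is exposed by :func:`table2_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import dendropy
import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, GAP
from .classifier import DOMAIN_LABELS, GOF, LOF, MutationRecord
from .hmm import GroupingScheme
from .io_core import (
    Alignment, AncestralReconstruction, Atom, Structure, read_tree,
    write_ancestral_states, write_alignment, write_structure_pdb,
)

logger = logging.getLogger(__name__)

PLANS = ("target-specific", "globally-conserved", "close-shared",
         "variable", "gap-block")

_GAP_MODES = ("others", "closest", "rest", "target")

#: Posterior mass placed on the true simulated state in emitted ancestral
#: state tables (remainder spread uniformly over the other 19 residues).
ASR_CONFIDENCE = 0.97


# ---------------------------------------------------------------------------
# Planted MSAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMsaSpec:
    """Study conditions for the planted-alignment generator.

    Defaults follow the toy-scale separation study: five subfamilies of
    20 sequences over 200 columns, with a plan mix that covers every
    category of the position-typing decision tree at least once.
    """

    n_subfamilies: int = 5
    n_sequences: int = 20
    n_holdout: int = 5
    n_columns: int = 200
    plan_fractions: tuple[tuple[str, float], ...] = (
        ("target-specific", 0.20),
        ("globally-conserved", 0.30),
        ("close-shared", 0.15),
        ("variable", 0.25),
        ("gap-block", 0.10),
    )
    noise: float = 0.02          # substitution rate of conserved columns
    variable_rate: float = 0.6   # substitution rate of variable columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies < 3:
            raise ValueError("need >= 3 subfamilies for target/closest/rest groups")
        fracs = dict(self.plan_fractions)
        if set(fracs) - set(PLANS):
            raise ValueError(f"unknown plans: {set(fracs) - set(PLANS)}")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("plan fractions must sum to 1")

    @property
    def subfamilies(self) -> tuple[str, ...]:
        return tuple(f"SF{i + 1}" for i in range(self.n_subfamilies))


@dataclass
class PlantedMsaResult:
    spec: PlantedMsaSpec
    scheme: GroupingScheme
    alignment: Alignment
    subfamily_alignments: dict[str, Alignment]
    holdout_sequences: dict[str, dict[str, str]]
    supertree: dendropy.Tree
    subfamily_trees: dict[str, dendropy.Tree]
    ancestral: dict[str, AncestralReconstruction]
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        """Write all fixtures in their standard on-disk formats."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, out / "alignment.fasta")
        for sf, aln in self.subfamily_alignments.items():
            write_alignment(aln, out / f"{sf}.fasta")
        with open(out / "supertree.nwk", "w") as fh:
            fh.write(self.supertree.as_string(schema="newick"))
        for sf, tree in self.subfamily_trees.items():
            with open(out / f"{sf}.nwk", "w") as fh:
                fh.write(tree.as_string(schema="newick"))
        for sf, asr in self.ancestral.items():
            write_ancestral_states(asr, out / f"{sf}_states.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _random_clade_newick(rng, leaves: list[str], prefix: str, counter: list[int]) -> str:
    """Random rooted binary subtree over ``leaves`` with labelled internals."""
    if len(leaves) == 1:
        return f"{leaves[0]}:{rng.uniform(0.05, 0.15):.6f}"
    split = int(rng.integers(1, len(leaves)))
    left = _random_clade_newick(rng, leaves[:split], prefix, counter)
    right = _random_clade_newick(rng, leaves[split:], prefix, counter)
    label = f"{prefix}_N{counter[0]}"
    counter[0] += 1
    return f"({left},{right}){label}:{rng.uniform(0.2, 0.5):.6f}"


def default_schemes(subfamilies: tuple[str, ...]) -> dict[str, GroupingScheme]:
    """Target/closest/rest groupings implied by the ladder supertree.

    Neighbouring clades on the ladder are each other's closest group; the
    remaining subfamilies form the rest.
    """
    out = {}
    for i, sf in enumerate(subfamilies):
        if i == 0:
            closest = (subfamilies[1],)
        elif i == 1:
            closest = (subfamilies[0],)
        else:
            closest = (subfamilies[i - 1],)
        rest = tuple(s for s in subfamilies if s != sf and s not in closest)
        out[sf] = GroupingScheme((sf,), closest, rest)
    return out


def _plan_assignments(spec: PlantedMsaSpec, rng) -> list[str]:
    counts = {}
    fracs = dict(spec.plan_fractions)
    total = 0
    for plan in PLANS:
        counts[plan] = int(round(fracs.get(plan, 0.0) * spec.n_columns))
        total += counts[plan]
    counts["globally-conserved"] += spec.n_columns - total  # absorb rounding
    plans = [p for p in PLANS for _ in range(counts[p])]
    return [plans[i] for i in rng.permutation(len(plans))]


def generate_subfamily_msas(spec: PlantedMsaSpec) -> PlantedMsaResult:
    """Simulate subfamily alignments, trees and ancestral tables with
    planted per-column signal.  Pure function of ``spec`` (seed included)."""
    rng = np.random.default_rng(spec.seed)
    subfams = spec.subfamilies
    n_total = spec.n_sequences + spec.n_holdout

    leaf_names = {
        sf: [f"{sf}_s{i}" for i in range(n_total)] for sf in subfams
    }
    clade_newicks = []
    for sf in subfams:
        counter = [0]
        # scatter leaf names over the clade so held-out leaves (the last
        # n_holdout names) are exchangeable with training leaves rather than
        # forming their own subclade
        order = [leaf_names[sf][i] for i in rng.permutation(n_total)]
        clade_newicks.append(
            _random_clade_newick(rng, order, sf, counter)
        )
    inner = f"({clade_newicks[0]},{clade_newicks[1]})SP1:0.200000"
    for k, clade in enumerate(clade_newicks[2:], start=2):
        inner = f"({inner},{clade})SP{k}:0.200000"
    # bifurcating root: last clade splits off at the root
    supertree_newick = inner.rsplit(")", 1)
    supertree_newick = supertree_newick[0] + ")SP0;"
    supertree = read_tree(data=supertree_newick)

    subfamily_trees = {
        sf: read_tree(data=clade + ";") for sf, clade in zip(subfams, clade_newicks)
    }

    # map: for each subfamily, its clade-root node in the supertree and the
    # preorder edges inside the clade
    clade_nodes: dict[str, list] = {}
    clade_root: dict[str, object] = {}
    for sf in subfams:
        mrca = supertree.mrca(taxon_labels=leaf_names[sf])
        clade_root[sf] = mrca
        nodes = [n for n in mrca.preorder_iter()]
        clade_nodes[sf] = nodes

    plans = _plan_assignments(spec, rng)
    aa = list(AMINO_ACIDS)

    # per column simulation
    node_states: dict[str, dict] = {sf: {} for sf in subfams}  # sf -> {node: list per column}
    for sf in subfams:
        node_states[sf] = {n: [] for n in clade_nodes[sf]}
    leaf_rows: dict[str, list[str]] = {name: [] for sf in subfams for name in leaf_names[sf]}
    truth_rows = []
    gap_mode_cycle = 0

    for col, plan in enumerate(plans):
        ref_aa = aa[rng.integers(20)]
        clade_root_state: dict[str, str] = {}
        clade_rate: dict[str, float] = {}
        gap_subfams: set[str] = set()
        gap_mode = ""
        planted_aa = ""

        if plan == "globally-conserved":
            for sf in subfams:
                clade_root_state[sf] = ref_aa
                clade_rate[sf] = spec.noise
        elif plan == "target-specific":
            planted_aa = aa[(AMINO_ACIDS.index(ref_aa) + 1 + int(rng.integers(18))) % 20]
            clade_root_state[subfams[0]] = planted_aa
            clade_rate[subfams[0]] = spec.noise * 0.5
            non_planted = [a for a in aa if a != planted_aa]
            for sf in subfams[1:]:
                clade_root_state[sf] = non_planted[int(rng.integers(19))]
                clade_rate[sf] = spec.variable_rate * 0.75
            ref_aa = planted_aa  # reference row belongs to the target clade
        elif plan == "close-shared":
            for sf in subfams[:2]:
                clade_root_state[sf] = ref_aa
                clade_rate[sf] = spec.noise
            for sf in subfams[2:]:
                alt = aa[(AMINO_ACIDS.index(ref_aa) + 1 + int(rng.integers(18))) % 20]
                clade_root_state[sf] = alt
                clade_rate[sf] = spec.noise
        elif plan == "variable":
            for sf in subfams:
                clade_root_state[sf] = aa[rng.integers(20)]
                clade_rate[sf] = spec.variable_rate
        else:  # gap-block
            gap_mode = _GAP_MODES[gap_mode_cycle % len(_GAP_MODES)]
            gap_mode_cycle += 1
            for sf in subfams:
                clade_root_state[sf] = ref_aa
                clade_rate[sf] = spec.noise
            if gap_mode == "others":
                gap_subfams = set(subfams[1:])
            elif gap_mode == "closest":
                gap_subfams = {subfams[1]}
            elif gap_mode == "rest":
                gap_subfams = set(subfams[2:])
            else:  # target (plus closest, so the column types as shared gap)
                gap_subfams = {subfams[0], subfams[1]}

        for sf in subfams:
            rate = clade_rate[sf]
            states = {clade_root[sf]: clade_root_state[sf]}
            for node in clade_nodes[sf]:
                if node is clade_root[sf]:
                    node_states[sf][node].append(states[node])
                    continue
                parent_state = states[node.parent_node]
                p_sub = 1.0 - np.exp(-rate * (node.edge.length or 0.0))
                if rng.random() < p_sub:
                    choices = [a for a in aa if a != parent_state]
                    state = choices[int(rng.integers(19))]
                else:
                    state = parent_state
                states[node] = state
                node_states[sf][node].append(state)
            for node in clade_nodes[sf]:
                if node.is_leaf():
                    name = node.taxon.label
                    if sf in gap_subfams and name != f"{subfams[0]}_s0":
                        leaf_rows[name].append(GAP)
                    else:
                        leaf_rows[name].append(states[node])

        truth_rows.append({
            "column": col,
            "reference_position": col + 1,
            "plan": plan,
            "gap_mode": gap_mode,
            "reference_aa": ref_aa,
            "target_aa": clade_root_state[subfams[0]],
        })

    # assemble alignments
    reference_id = f"{subfams[0]}_s0"
    train_rows: dict[str, str] = {}
    holdout: dict[str, dict[str, str]] = {sf: {} for sf in subfams}
    for sf in subfams:
        for i, name in enumerate(leaf_names[sf]):
            row = "".join(leaf_rows[name])
            if i < spec.n_sequences:
                train_rows[name] = row
            else:
                holdout[sf][name] = row.replace(GAP, "")
    alignment = Alignment(train_rows, reference_id)
    subfamily_alignments = {}
    for sf in subfams:
        rows = {n: train_rows[n] for n in leaf_names[sf][: spec.n_sequences]}
        subfamily_alignments[sf] = Alignment(rows, leaf_names[sf][0])

    # ancestral tables per subfamily (internal nodes of the clade trees)
    ancestral = {}
    for sf in subfams:
        probs: dict[str, np.ndarray] = {}
        for node in clade_nodes[sf]:
            if node.is_leaf():
                continue
            mat = np.full((spec.n_columns, 20), (1.0 - ASR_CONFIDENCE) / 19.0)
            states = node_states[sf][node]
            idx = np.fromiter((AMINO_ACIDS.index(s) for s in states), int)
            mat[np.arange(spec.n_columns), idx] = ASR_CONFIDENCE
            probs[node.label] = mat
        ancestral[sf] = AncestralReconstruction(probs, spec.n_columns)

    schemes = default_schemes(subfams)
    return PlantedMsaResult(
        spec=spec,
        scheme=schemes[subfams[0]],
        alignment=alignment,
        subfamily_alignments=subfamily_alignments,
        holdout_sequences=holdout,
        supertree=supertree,
        subfamily_trees=subfamily_trees,
        ancestral=ancestral,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Planted structure ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContact:
    """One contact change: residue pair and its distance in each state (A)."""

    residue_a: int
    residue_b: int
    active_distance: float = 3.0
    inactive_distance: float = 6.0


@dataclass(frozen=True)
class PlantedStructureSpec:
    """Study conditions for the structure-ensemble generator.

    Ensemble sizes default to 7 active / 5 inactive structures.  Residues
    sit on a widely spaced line so that no contact exists except the planted
    ones; each planted pair's side-chain geometry places at least one atom
    pair in the linear kernel zone in one of the states.
    """

    n_residues: int = 60
    contacts: tuple[PlantedContact, ...] = (PlantedContact(10, 40),)
    jitter: float = 0.05
    n_active: int = 7
    n_inactive: int = 5
    chain: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        used: set[int] = set()
        for c in self.contacts:
            for r in (c.residue_a, c.residue_b):
                if not 0 <= r < self.n_residues:
                    raise ValueError(f"planted residue {r} out of range")
                if r in used:
                    raise ValueError("planted pairs must use distinct residues")
                used.add(r)
            if abs(c.residue_a - c.residue_b) < 5:
                raise ValueError("planted pairs must be >= 5 residues apart "
                                 "(closer pairs fall under the neighbour rule)")


@dataclass
class PlantedStructureResult:
    spec: PlantedStructureSpec
    active: list[Structure]
    inactive: list[Structure]
    truth: pd.DataFrame  # planted residue pairs

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.active + self.inactive:
            write_structure_pdb(s, out / f"{s.structure_id}.pdb")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


_RESIDUE_SPACING = 10.0
_ATOM_OFFSETS = (
    ("N", (-1.2, -0.8, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (1.2, -0.8, 0.0)),
    ("O", (1.9, -1.9, 0.0)),
    ("CB", (0.0, 1.5, 0.0)),
    ("CG", (0.0, 3.0, 0.0)),
)


def _base_positions(spec: PlantedStructureSpec, state: str) -> dict[int, np.ndarray]:
    """Residue base (CA) positions; planted partners are lifted above their
    counterpart so that CB-CB distance equals the planted state distance."""
    bases = {
        r: np.array([_RESIDUE_SPACING * r, 0.0, 0.0]) for r in range(spec.n_residues)
    }
    for c in spec.contacts:
        d = c.active_distance if state == "active" else c.inactive_distance
        anchor = min(c.residue_a, c.residue_b)
        moved = max(c.residue_a, c.residue_b)
        bases[moved] = bases[anchor] + np.array([0.0, d, 0.0])
    return bases


def generate_structure_ensembles(spec: PlantedStructureSpec) -> PlantedStructureResult:
    """Active/inactive toy ensembles differing only in the planted contacts."""
    rng = np.random.default_rng(spec.seed)
    structures: dict[str, list[Structure]] = {"active": [], "inactive": []}
    for state, count in (("active", spec.n_active), ("inactive", spec.n_inactive)):
        bases = _base_positions(spec, state)
        for k in range(count):
            atoms = []
            for r in range(spec.n_residues):
                for name, offset in _ATOM_OFFSETS:
                    pos = bases[r] + np.array(offset)
                    pos = pos + rng.normal(0.0, spec.jitter, 3)
                    atoms.append(Atom(spec.chain, r + 1, "ALA", name,
                                      float(pos[0]), float(pos[1]), float(pos[2])))
            structures[state].append(
                Structure(f"{state}_{k}", state, atoms)
            )
    truth = pd.DataFrame([
        {
            "residue_a": min(c.residue_a, c.residue_b) + 1,
            "residue_b": max(c.residue_a, c.residue_b) + 1,
            "active_distance": c.active_distance,
            "inactive_distance": c.inactive_distance,
        }
        for c in spec.contacts
    ])
    return PlantedStructureResult(spec, structures["active"], structures["inactive"], truth)


# ---------------------------------------------------------------------------
# Planted mutation datasets
# ---------------------------------------------------------------------------

def generate_mutation_dataset(
    msa: PlantedMsaResult,
    n: int = 300,
    label_noise: float = 0.1,
    gof_fraction: float = 94 / 337,
    seed: int = 0,
) -> pd.DataFrame:
    """Mutation table drawn from the planted column classes.

    GoF rows substitute, at a target-specific column, the target residue by
    one tolerated in the non-target subfamilies; LoF rows substitute, at a
    globally conserved column, the conserved residue by one unseen in any
    subfamily.  Labels are then flipped with probability ``label_noise``.
    The GoF fraction defaults to the clinical-literature class balance
    (94 GoF / 243 LoF).  Columns: position, aa0, aa1, label, true_label.
    """
    rng = np.random.default_rng(seed)
    truth = msa.truth
    target_sf = msa.spec.subfamilies[0]
    other_sfs = msa.spec.subfamilies[1:]
    gof_positions = truth.loc[truth["plan"] == "target-specific", "reference_position"].to_numpy()
    lof_positions = truth.loc[truth["plan"] == "globally-conserved", "reference_position"].to_numpy()
    if len(gof_positions) == 0 or len(lof_positions) == 0:
        raise ValueError("truth table lacks planted GoF or LoF positions")

    target_aln = msa.subfamily_alignments[target_sf]
    n_gof = int(round(n * gof_fraction))
    rows = []
    replace_needed = n_gof > len(gof_positions) or (n - n_gof) > len(lof_positions)
    if replace_needed:
        logger.info("sampling planted positions with replacement (n=%d)", n)
    for true_label, count, positions in (
        (GOF, n_gof, gof_positions), (LOF, n - n_gof, lof_positions)
    ):
        chosen = rng.choice(positions, size=count, replace=True)
        for pos in chosen:
            col_idx = int(pos) - 1
            aa0 = msa.alignment.reference_sequence[col_idx]
            target_col = target_aln.column(col_idx)
            observed_target = set(target_col) - {GAP}
            if true_label == GOF:
                # residue common in other subfamilies but unseen in target
                pooled = "".join(
                    msa.subfamily_alignments[sf].column(col_idx) for sf in other_sfs
                )
                candidates = [
                    (pooled.count(a), a) for a in AMINO_ACIDS
                    if a not in observed_target and pooled.count(a) > 0
                ]
                if candidates:
                    aa1 = max(candidates)[1]
                else:
                    aa1 = next(a for a in AMINO_ACIDS if a not in observed_target)
            else:
                observed_any = set()
                for sf in msa.spec.subfamilies:
                    observed_any |= set(msa.subfamily_alignments[sf].column(col_idx))
                unseen = [a for a in AMINO_ACIDS if a not in observed_any]
                aa1 = unseen[int(rng.integers(len(unseen)))] if unseen else (
                    next(a for a in AMINO_ACIDS if a != aa0)
                )
            if aa1 == aa0:
                aa1 = next(a for a in AMINO_ACIDS if a != aa0 and a not in observed_target)
            label = true_label
            if rng.random() < label_noise:
                label = LOF if true_label == GOF else GOF
            rows.append({"position": int(pos), "aa0": aa0, "aa1": aa1,
                         "label": label, "true_label": true_label})
    df = pd.DataFrame(rows)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def synthetic_domain_map(n_positions: int) -> dict[int, str]:
    """Deterministic block domain labels for synthetic reference coordinates."""
    block = max(1, n_positions // len(DOMAIN_LABELS))
    return {
        p: DOMAIN_LABELS[min((p - 1) // block, len(DOMAIN_LABELS) - 1)]
        for p in range(1, n_positions + 1)
    }


def mutation_records(df: pd.DataFrame) -> list[MutationRecord]:
    return [
        MutationRecord(int(r.position), r.aa0, r.aa1, r.label)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Packaged in-paper fixture
# ---------------------------------------------------------------------------

def table2_fixture() -> pd.DataFrame:
    """The packaged 22-row literature validation table.

    Columns: ``mutation`` (protein nomenclature), ``cause`` (hypercalcemia /
    hypocalcemia), ``prediction`` (gain-of-function / loss-of-function) and
    ``starred`` (1 where the printed prediction matches the phenotype-derived
    ground truth).
    """
    with resources.files("subspec.data").joinpath("table2_predictions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["starred"] = df["starred"].astype(bool)
    return df
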