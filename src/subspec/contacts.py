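"""Residue-residue contact scores (RRCS) and activation-network analysis.

Class C GPCRs rearrange subtly on activation, so residue-level contact
scores are computed two ways: the classic residue-level sum over heavy-atom
pairs, and a higher-resolution *atom-level* variant that treats every heavy
atom as its own unit, resolving which atoms of a residue pair actually move.

The contact kernel is a clipped linear ramp on inter-atom distance: 1 at or
below ``d_min`` = 3.23 A, 0 at or above ``d_max`` = 4.63 A, linear in
between.  For sequence neighbours (residue separation < 5 within a chain)
main-chain atoms are excluded, so trivially persistent backbone contacts do
not drown the signal.

Contact changes between an active and an inactive structure ensemble are
screened per unit pair with Welch's t test (no multiple-testing adjustment;
pairs scoring zero everywhere are skipped, zero-variance pairs get p = 1),
and significant atom-level changes are aggregated into a residue-level
activation network in which edge multiplicity counts the atom-level events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io_core import Structure, welch_t_test

logger = logging.getLogger(__name__)

D_MIN = 3.23
D_MAX = 4.63
NEIGHBOR_SEPARATION = 5


def atom_pair_score(d: float, d_min: float = D_MIN, d_max: float = D_MAX) -> float:
    """Clipped linear contact kernel on distance (Angstrom), in [0, 1]."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d <= d_min:
        return 1.0
    if d >= d_max:
        return 0.0
    return (d_max - d) / (d_max - d_min)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric nonzero contact scores of one structure.

    Keys are canonically ordered unit pairs; a unit is ``(chain, resseq)``
    at residue level or ``(chain, resseq, atom_name)`` at atom level.
    """

    structure_id: str
    state: str
    level: str      # "residue" | "atom"
    scope: str      # "intra-protomer" | "inter-protomer"
    scores: dict[tuple, float]

    def score(self, unit_a, unit_b) -> float:
        key = (unit_a, unit_b) if unit_a <= unit_b else (unit_b, unit_a)
        return self.scores.get(key, 0.0)


def rrcs(
    structure: Structure,
    level: str = "residue",
    scope: str = "intra-protomer",
    neighbor_rule: bool = True,
) -> ContactMatrix:
    """Contact matrix of one structure.

    ``level='residue'`` sums the kernel over heavy-atom pairs of each residue
    pair; ``level='atom'`` keeps each heavy-atom pair as its own unit pair.
    ``scope`` restricts to same-chain (intra-protomer) or cross-chain
    (inter-protomer) pairs.  ``neighbor_rule`` applies the main-chain
    exclusion for residue separation < 5 within a chain.
    """
    if level not in ("residue", "atom"):
        raise ValueError(f"unknown level {level!r}")
    if scope not in ("intra-protomer", "inter-protomer"):
        raise ValueError(f"unknown scope {scope!r}")
    atoms = structure.atoms
    if not atoms:
        raise ValueError(f"structure {structure.structure_id} has no atoms")
    xyz = structure.coords
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(D_MAX, output_type="ndarray")
    scores: dict[tuple, float] = {}
    for ia, ib in pairs:
        a, b = atoms[ia], atoms[ib]
        if a.chain == b.chain:
            if scope == "inter-protomer":
                continue
            if a.resseq == b.resseq:
                continue
            if (
                neighbor_rule
                and abs(a.resseq - b.resseq) < NEIGHBOR_SEPARATION
                and (a.is_mainchain or b.is_mainchain)
            ):
                continue
        elif scope == "intra-protomer":
            continue
        d = float(np.linalg.norm(xyz[ia] - xyz[ib]))
        s = atom_pair_score(d)
        if s <= 0.0:
            continue
        if level == "residue":
            ua, ub = (a.chain, a.resseq), (b.chain, b.resseq)
        else:
            ua, ub = (a.chain, a.resseq, a.name), (b.chain, b.resseq, b.name)
        key = (ua, ub) if ua <= ub else (ub, ua)
        scores[key] = scores.get(key, 0.0) + s
    return ContactMatrix(structure.structure_id, structure.state, level, scope, scores)


@dataclass(frozen=True)
class ContactChange:
    """A unit pair with a significant active-vs-inactive score change."""

    unit_a: tuple
    unit_b: tuple
    active_scores: tuple[float, ...]
    inactive_scores: tuple[float, ...]
    t: float
    p: float
    direction: str  # "increase" | "decrease"
    level: str
    scope: str


def contact_change_test(
    active: list[ContactMatrix],
    inactive: list[ContactMatrix],
    alpha: float = 0.01,
) -> list[ContactChange]:
    """Welch-screen every unit pair seen in any matrix of either ensemble.

    A pair absent from a structure scores 0 there.  Pairs scoring zero in
    every structure are not tested; pairs with zero pooled variance get
    p = 1 (via :func:`welch_t_test`) and are therefore never reported.
    Retained pairs have p < ``alpha``; direction follows the mean
    active-minus-inactive difference.  No multiple-testing adjustment is
    applied.
    """
    if len(active) < 2 or len(inactive) < 2:
        raise ValueError("need >= 2 structures per state")
    levels = {m.level for m in active + inactive}
    scopes = {m.scope for m in active + inactive}
    if len(levels) != 1 or len(scopes) != 1:
        raise ValueError("all matrices must share level and scope")
    level, scope = levels.pop(), scopes.pop()

    keys: set[tuple] = set()
    for m in active + inactive:
        keys.update(m.scores)
    changes: list[ContactChange] = []
    n_zero_var = 0
    for key in sorted(keys):
        ua, ub = key
        a_scores = np.array([m.scores.get(key, 0.0) for m in active])
        i_scores = np.array([m.scores.get(key, 0.0) for m in inactive])
        scale = max(1.0, a_scores.max(), i_scores.max())
        if a_scores.var(ddof=1) + i_scores.var(ddof=1) <= (1e-12 * scale) ** 2:
            n_zero_var += 1  # constant pair: p = 1, never reported
            continue
        t, p = welch_t_test(a_scores, i_scores)
        if p < alpha:
            diff = a_scores.mean() - i_scores.mean()
            changes.append(ContactChange(
                ua, ub, tuple(a_scores), tuple(i_scores), t, p,
                "increase" if diff > 0 else "decrease", level, scope,
            ))
    if n_zero_var:
        logger.warning(
            "contact_change_test: %d pair(s) with zero within-state variance "
            "(p set to 1)", n_zero_var,
        )
    return changes


def _residue_pair(change: ContactChange, protomer_map: dict[str, str] | None):
    """Residue-pair edge key of a change, collapsing protomer symmetry.

    With a protomer map (chain -> protomer id) the key ignores which
    protomer the pair was observed in, so symmetric duplicates of a
    homodimer become one edge.
    """
    def residue(unit):
        chain, resseq = unit[0], unit[1]
        if protomer_map is not None:
            return ("*", resseq)
        return (chain, resseq)

    ra, rb = residue(change.unit_a), residue(change.unit_b)
    return (ra, rb) if ra <= rb else (rb, ra)


def build_network(
    changes: list[ContactChange],
    protomer_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Aggregate significant changes into a residue-level activation network.

    Atom-level intra-protomer changes map to residue-pair edges whose
    ``multiplicity`` counts the distinct significant atom pairs; residue-level
    dimer-interface changes contribute one edge each.  Symmetric duplicates
    across protomers (A->B vs B->A) collapse onto a single edge when a
    ``protomer_map`` is provided.  Edge attribute ``interface`` is
    ``intra-protomer`` or ``dimer-interface``.
    """
    g = nx.Graph()
    seen_events: set[tuple] = set()
    for ch in changes:
        interface = "intra-protomer" if ch.scope == "intra-protomer" else "dimer-interface"
        ra, rb = _residue_pair(ch, protomer_map)
        if ch.level == "atom":
            event = (ra, rb, ch.unit_a[2], ch.unit_b[2])
        else:
            event = (ra, rb, None, None)
        if event in seen_events:
            continue  # symmetric duplicate of the same atom/residue pair
        seen_events.add(event)
        if g.has_edge(ra, rb):
            g[ra][rb]["multiplicity"] += 1
            g[ra][rb]["directions"].append(ch.direction)
        else:
            g.add_edge(ra, rb, multiplicity=1, interface=interface,
                       directions=[ch.direction])
    return g


def significant_change_counts(network: nx.Graph) -> dict:
    """Per-residue count of significant changes (sum of incident multiplicities)."""
    counts: dict = {}
    for a, b, data in network.edges(data=True):
        counts[a] = counts.get(a, 0) + data["multiplicity"]
        counts[b] = counts.get(b, 0) + data["multiplicity"]
    return counts


def changes_to_table(changes: list[ContactChange]):
    import pandas as pd

    return pd.DataFrame([
        {
            "unit_a": "/".join(map(str, ch.unit_a)),
            "unit_b": "/".join(map(str, ch.unit_b)),
            "mean_active": float(np.mean(ch.active_scores)),
            "mean_inactive": float(np.mean(ch.inactive_scores)),
            "t": ch.t,
            "p": ch.p,
            "direction": ch.direction,
            "level": ch.level,
            "scope": ch.scope,
        }
        for ch in changes
    ])
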