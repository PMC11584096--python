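"""Gradient-boosted GoF/LoF mutation classification.

Missense mutations of the reference receptor are labelled gain-of-function
(GoF, clinically hypocalcemia) or loss-of-function (LoF, hypercalcemia).
The working hypothesis is evolutionary: a substitution to a residue that is
tolerated in neighbouring subfamilies but not in the target subfamily tends
to activate, whereas substituting a residue conserved across all subfamilies
tends to inactivate.

Features per mutation: conservation (column frequency) of the reference and
substituted residue in each subfamily alignment, BLOSUM62 row encodings of
both residues, nine physico-chemical scale values for both residues, and a
one-hot domain label of the position.  The replication protocol is a
stratified 80/20 train/test split, five 25% validation subsamples of the
training split for greedy step-by-step hyper-parameter tuning of an XGBoost
model (depth 2, 200 rounds), repeated over independent replications.
Continuous features are z-scored with training-split statistics only.

Substitutions to residues already observed at that column of the target
(CaSR) alignment are overlaid as *neutral* regardless of the model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import train_test_split

from .alphabet import AMINO_ACIDS, AA_INDEX, GAP
from .hmm import _BLOSUM62
from .io_core import Alignment

logger = logging.getLogger(__name__)

GOF, LOF, NEUTRAL = "GoF", "LoF", "neutral"

#: Domain vocabulary of the reference receptor.
DOMAIN_LABELS: tuple[str, ...] = (
    "VFT-LB1", "VFT-LB2", "CRD",
    "TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7",
    "ECL1", "ECL2", "ECL3", "ICL1", "ICL2", "ICL3",
    "cytoplasmic",
)

PHYSCHEM_SCALES = (
    "zimmerman_polarity", "average_flexibility", "dayhoff_mutability",
    "average_buried_area", "doolittle_hydropathicity", "atomic_weight_ratio",
    "molecular_weight", "bulkiness", "tm_tendency",
)

_MUTATION_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def load_physchem_table() -> pd.DataFrame:
    """The packaged 20-residue physico-chemical scale table, indexed by residue."""
    with resources.files("subspec.data").joinpath("physchem.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("aa")
    return df.loc[list(AMINO_ACIDS), list(PHYSCHEM_SCALES)]


# Approximate domain boundaries of the human CaSR (1078 aa), for the worked
# examples; synthetic datasets carry their own generated domain maps.
_CASR_SEGMENTS = (
    (1, 335, "VFT-LB1"), (336, 541, "VFT-LB2"), (542, 612, "CRD"),
    (613, 637, "TM1"), (638, 649, "ICL1"), (650, 674, "TM2"),
    (675, 680, "ECL1"), (681, 705, "TM3"), (706, 724, "ICL2"),
    (725, 749, "TM4"), (750, 769, "ECL2"), (770, 793, "TM5"),
    (794, 806, "ICL3"), (807, 828, "TM6"), (829, 832, "ECL3"),
    (833, 862, "TM7"), (863, 1078, "cytoplasmic"),
)


def casr_domain_map() -> dict[int, str]:
    """Approximate position -> domain label map for the human CaSR."""
    return {p: label for start, end, label in _CASR_SEGMENTS
            for p in range(start, end + 1)}


@dataclass(frozen=True)
class MutationRecord:
    """A missense mutation in 1-based reference coordinates."""

    position: int
    aa0: str
    aa1: str
    label: str | None = None  # "GoF" | "LoF" | None

    def __post_init__(self) -> None:
        if self.aa0 not in AA_INDEX or self.aa1 not in AA_INDEX:
            raise ValueError(f"invalid residues {self.aa0!r}->{self.aa1!r}")
        if self.aa0 == self.aa1:
            raise ValueError("aa0 and aa1 must differ")
        if self.label is not None and self.label not in (GOF, LOF):
            raise ValueError(f"label must be GoF or LoF, got {self.label!r}")

    @classmethod
    def parse(cls, text: str, label: str | None = None) -> "MutationRecord":
        """Parse protein-level nomenclature like ``p.I857S``."""
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation {text!r}")
        return cls(int(m.group(2)), m.group(1), m.group(3), label)


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def conservation_score(aln: Alignment, position: int, aa: str) -> float:
    """Frequency of ``aa`` in the column at a 1-based reference position.

    Gaps stay in the denominator.  The alignment must be reference-gap
    removed so positions index columns directly.
    """
    if not 1 <= position <= aln.n_columns:
        raise ValueError(f"position {position} outside 1..{aln.n_columns}")
    col = aln.column(position - 1)
    return col.count(aa) / len(col)


def feature_names(subfamilies: tuple[str, ...]) -> list[str]:
    names: list[str] = []
    for sf in subfamilies:
        names += [f"cons_{sf}_aa0", f"cons_{sf}_aa1"]
    names += [f"blosum_aa0_{a}" for a in AMINO_ACIDS]
    names += [f"blosum_aa1_{a}" for a in AMINO_ACIDS]
    for scale in PHYSCHEM_SCALES:
        names += [f"{scale}_aa0", f"{scale}_aa1"]
    names += [f"domain_{d}" for d in DOMAIN_LABELS]
    names += [f"cov_{sf}" for sf in subfamilies]
    return names


def build_feature_row(
    record: MutationRecord,
    alignments: dict[str, Alignment],
    domain_map: dict[int, str],
    physchem: pd.DataFrame | None = None,
) -> pd.Series:
    """Deterministic fixed-order numeric feature vector for one mutation.

    Subfamily alignments not covering the position contribute zeros with the
    corresponding ``cov_<subfamily>`` flag cleared.
    """
    if physchem is None:
        physchem = load_physchem_table()
    subfamilies = tuple(alignments)
    values: dict[str, float] = {}
    for sf, aln in alignments.items():
        covered = 1 <= record.position <= aln.n_columns
        values[f"cov_{sf}"] = float(covered)
        values[f"cons_{sf}_aa0"] = (
            conservation_score(aln, record.position, record.aa0) if covered else 0.0
        )
        values[f"cons_{sf}_aa1"] = (
            conservation_score(aln, record.position, record.aa1) if covered else 0.0
        )
    for a in AMINO_ACIDS:
        values[f"blosum_aa0_{a}"] = float(_BLOSUM62[record.aa0][a])
        values[f"blosum_aa1_{a}"] = float(_BLOSUM62[record.aa1][a])
    for scale in PHYSCHEM_SCALES:
        values[f"{scale}_aa0"] = float(physchem.loc[record.aa0, scale])
        values[f"{scale}_aa1"] = float(physchem.loc[record.aa1, scale])
    domain = domain_map.get(record.position)
    for d in DOMAIN_LABELS:
        values[f"domain_{d}"] = float(d == domain)
    return pd.Series(values, index=feature_names(subfamilies), dtype=float)


def build_feature_matrix(
    records: list[MutationRecord],
    alignments: dict[str, Alignment],
    domain_map: dict[int, str],
) -> pd.DataFrame:
    physchem = load_physchem_table()
    rows = [build_feature_row(r, alignments, domain_map, physchem) for r in records]
    return pd.DataFrame(rows).reset_index(drop=True)


def _continuous_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if not c.startswith(("domain_", "cov_"))]


def normalize_features(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, list[pd.DataFrame], pd.Series, pd.Series]:
    """Z-score continuous features with training statistics only.

    One-hot domain and coverage-flag columns pass through untouched.
    Zero-variance training columns are set to 0 everywhere with a warning.
    Returns the scaled training frame, scaled other frames, and the training
    means and (population) standard deviations used.
    """
    cols = _continuous_columns(train)
    mean = train[cols].mean()
    sd = train[cols].std(ddof=0)
    zero_var = sd[sd == 0.0].index
    if len(zero_var):
        logger.warning("%d zero-variance feature(s) left at 0: %s",
                       len(zero_var), list(zero_var)[:5])
    safe_sd = sd.replace(0.0, 1.0)

    def _scale(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[cols] = (df[cols] - mean) / safe_sd
        out[zero_var] = 0.0
        return out

    return _scale(train), [_scale(o) for o in others], mean, sd


# ---------------------------------------------------------------------------
# Splitting protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """One replication of the stratified splitting protocol."""

    replication: int
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]  # (fit_idx, val_idx) x 5


def make_splits(
    labels, n_replications: int = 50, seed: int = 0, n_folds: int = 5
) -> list[SplitPlan]:
    """Stratified 80/20 splits with five 25% validation subsamples each.

    Splits are made on indices before any feature normalization, so scaling
    statistics can never leak from test rows.  The same seed reproduces the
    same plans exactly.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to stratify")
    idx = np.arange(len(y))
    plans = []
    for rep in range(n_replications):
        rep_seed = (seed + 1_000_003 * (rep + 1)) % (2**31 - 1)
        train_idx, test_idx = train_test_split(
            idx, test_size=0.2, stratify=y, random_state=rep_seed
        )
        folds = []
        for f in range(n_folds):
            fit_idx, val_idx = train_test_split(
                train_idx, test_size=0.25, stratify=y[train_idx],
                random_state=rep_seed + f + 1,
            )
            folds.append((fit_idx, val_idx))
        plans.append(SplitPlan(rep, rep_seed, train_idx, test_idx, tuple(folds)))
    return plans


# ---------------------------------------------------------------------------
# Tuning grid and training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningGrid:
    """Ordered one-parameter-at-a-time tuning grid.

    Parameters are tuned greedily in the stated order, reusing the same five
    validation folds for every step; ties select the smallest candidate.
    Tree depth is fixed at 2 and boosting rounds at 200.
    """

    steps: tuple[tuple[str, tuple[float, ...]], ...]
    max_depth: int = 2
    n_rounds: int = 200

    @classmethod
    def default(cls) -> "TuningGrid":
        return cls(steps=(
            ("learning_rate", tuple(np.round(np.arange(1, 101) * 1e-5, 8))),
            ("gamma", (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)),
            ("subsample", tuple(np.round(np.arange(0.5, 1.0001, 0.05), 2))),
            ("colsample_bytree", tuple(np.round(np.arange(0.5, 1.0001, 0.05), 2))),
            ("min_child_weight", (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)),
            ("reg_lambda", (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)),
            ("reg_alpha", (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)),
        ))

    @classmethod
    def reduced(cls) -> "TuningGrid":
        """A coarse grid covering the same parameters for small studies."""
        return cls(steps=(
            ("learning_rate", (2e-4, 5e-4, 1e-3)),
            ("gamma", (0.0, 0.3)),
            ("subsample", (0.7, 1.0)),
            ("colsample_bytree", (0.7, 1.0)),
            ("min_child_weight", (1.0, 3.0)),
            ("reg_lambda", (0.0, 1.0)),
            ("reg_alpha", (0.0, 1.0)),
        ))

    @classmethod
    def fixed(cls, **params) -> "TuningGrid":
        """Single-candidate grid (no search), for quick fits."""
        defaults = {"learning_rate": 1e-3, "gamma": 0.0, "subsample": 1.0,
                    "colsample_bytree": 1.0, "min_child_weight": 1.0,
                    "reg_lambda": 1.0, "reg_alpha": 0.0}
        defaults.update(params)
        return cls(steps=tuple((k, (float(v),)) for k, v in defaults.items()))


@dataclass
class TrainedModel:
    model: object
    params: dict[str, float]
    tuning_trace: list[tuple[str, float, float]] = field(default_factory=list)

    def predict_proba_gof(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(X.to_numpy(float))[:, 1]


def _new_booster(params: dict[str, float], max_depth: int, n_rounds: int, seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        max_depth=max_depth, n_estimators=n_rounds, tree_method="hist",
        n_jobs=1, random_state=seed, eval_metric="logloss", **params,
    )


def tune_and_train(
    X: pd.DataFrame, y, plan: SplitPlan, grid: TuningGrid | None = None
) -> TrainedModel:
    """Greedy step-by-step tuning on the plan's validation folds, then a
    final fit on the full training split.

    ``X`` and ``y`` cover the whole dataset; the plan's indices select the
    training split and folds (test rows are never touched).  ``y`` holds
    "GoF"/"LoF" labels; internally GoF is encoded 1.  Features are
    normalized inside every fold and for the final fit with the fitting
    rows' statistics only.
    """
    if grid is None:
        grid = TuningGrid.default()
    y = np.asarray(y)
    y_bin = (y == GOF).astype(int)
    params: dict[str, float] = {name: cands[0] for name, cands in grid.steps}
    trace: list[tuple[str, float, float]] = []

    fold_data = []
    for fit_idx, val_idx in plan.folds:
        X_fit, (X_val,), _, _ = normalize_features(X.iloc[fit_idx], X.iloc[val_idx])
        fold_data.append((X_fit.to_numpy(float), y_bin[fit_idx],
                          X_val.to_numpy(float), y_bin[val_idx]))

    def mean_val_auroc(p: dict[str, float]) -> float:
        scores = []
        for Xf, yf, Xv, yv in fold_data:
            clf = _new_booster(p, grid.max_depth, grid.n_rounds, plan.seed)
            clf.fit(Xf, yf)
            scores.append(_skm.roc_auc_score(yv, clf.predict_proba(Xv)[:, 1]))
        return float(np.mean(scores))

    for name, candidates in grid.steps:
        best_value, best_score = None, -np.inf
        for cand in sorted(candidates):
            trial = dict(params, **{name: cand})
            score = mean_val_auroc(trial)
            if score > best_score:  # strict: ties keep the smallest candidate
                best_value, best_score = cand, score
        params[name] = best_value
        trace.append((name, best_value, best_score))

    X_train, _, _, _ = normalize_features(X.iloc[plan.train_idx])
    clf = _new_booster(params, grid.max_depth, grid.n_rounds, plan.seed)
    clf.fit(X_train.to_numpy(float), y_bin[plan.train_idx])
    return TrainedModel(clf, params, trace)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(y_true, scores_gof, threshold: float = 0.5) -> dict[str, float]:
    """AUROC, AUPR, accuracy and F1 from GoF-probability scores.

    AUPR and the headline F1 take LoF (the majority clinical class) as the
    positive class; per-class F1 values are also reported.  AUROC and AUPR
    require both classes present.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores_gof, float)
    y_gof = (y == GOF).astype(int) if y.dtype.kind in "UO" else y.astype(int)
    if len(np.unique(y_gof)) < 2:
        raise ValueError("both classes required for AUROC/AUPR")
    pred_gof = (s >= threshold).astype(int)
    f1_lof = _skm.f1_score(1 - y_gof, 1 - pred_gof, zero_division=0)
    f1_gof = _skm.f1_score(y_gof, pred_gof, zero_division=0)
    return {
        "auroc": float(_skm.roc_auc_score(y_gof, s)),
        "aupr": float(_skm.average_precision_score(1 - y_gof, 1.0 - s)),
        "accuracy": float(_skm.accuracy_score(y_gof, pred_gof)),
        "f1": float(f1_lof),
        "f1_lof": float(f1_lof),
        "f1_gof": float(f1_gof),
    }


def predict_with_neutral_overlay(
    model: TrainedModel,
    records: list[MutationRecord],
    features: pd.DataFrame,
    casr_aln: Alignment,
    threshold: float = 0.5,
) -> list[str]:
    """GoF/LoF/neutral call per substitution.

    A substitution to a residue already observed at that column of the
    target (CaSR) alignment is neutral regardless of the model; otherwise
    the model's GoF probability is thresholded at 0.5.
    """
    X, _, _, _ = normalize_features(features)
    probs = model.predict_proba_gof(X)
    out = []
    for rec, p in zip(records, probs):
        col = casr_aln.column(rec.position - 1)
        if rec.aa1 in col:
            out.append(NEUTRAL)
        else:
            out.append(GOF if p >= threshold else LOF)
    return out


def scan_substitutions(
    casr_aln: Alignment, positions: range | None = None
) -> list[MutationRecord]:
    """All 19 substitutions per reference position (for full-scan exports)."""
    ref = casr_aln.reference_sequence
    if positions is None:
        positions = range(1, len(ref) + 1)
    records = []
    for pos in positions:
        aa0 = ref[pos - 1]
        if aa0 == GAP:
            continue
        for aa1 in AMINO_ACIDS:
            if aa1 != aa0:
                records.append(MutationRecord(pos, aa0, aa1))
    return records


# ---------------------------------------------------------------------------
# Replication pipeline and the in-table validation fixture
# ---------------------------------------------------------------------------

def run_replications(
    features: pd.DataFrame,
    labels,
    n_replications: int,
    grid: TuningGrid | None = None,
    seed: int = 0,
    eval_labels=None,
) -> pd.DataFrame:
    """Full protocol: split, tune, train, evaluate; one row per replication.

    ``labels`` drive stratification, tuning and training.  ``eval_labels``
    (defaults to ``labels``) are the labels metrics are computed against;
    passing uncorrupted ground truth here measures recovery of the planted
    rule under label noise rather than agreement with the noise itself.
    """
    y = np.asarray(labels)
    y_eval = y if eval_labels is None else np.asarray(eval_labels)
    plans = make_splits(y, n_replications, seed)
    rows = []
    for plan in plans:
        model = tune_and_train(features, y, plan, grid)
        X_train_raw = features.iloc[plan.train_idx]
        _, (X_test,), _, _ = normalize_features(X_train_raw, features.iloc[plan.test_idx])
        test_metrics = evaluate(y_eval[plan.test_idx], model.predict_proba_gof(X_test))
        X_train, _, _, _ = normalize_features(X_train_raw)
        train_metrics = evaluate(y_eval[plan.train_idx], model.predict_proba_gof(X_train))
        rows.append({
            "replication": plan.replication,
            "train_auroc": train_metrics["auroc"],
            "test_auroc": test_metrics["auroc"],
            "train_aupr": train_metrics["aupr"],
            "test_aupr": test_metrics["aupr"],
            "test_accuracy": test_metrics["accuracy"],
            "test_f1": test_metrics["f1"],
        })
    return pd.DataFrame(rows)


def score_table2_fixture() -> dict[str, float]:
    """Score the packaged 22-mutation literature validation table.

    Ground truth derives from the phenotype column (hypercalcemia -> LoF,
    hypocalcemia -> GoF) and is compared with the printed model prediction;
    F1 takes LoF as the positive class.
    """
    from .synthetic import table2_fixture

    df = table2_fixture()
    truth = np.where(df["cause"] == "hypercalcemia", LOF, GOF)
    pred = np.where(df["prediction"] == "loss-of-function", LOF, GOF)
    correct = truth == pred
    tp = int(((truth == LOF) & (pred == LOF)).sum())
    fp = int(((truth == GOF) & (pred == LOF)).sum())
    fn = int(((truth == LOF) & (pred == GOF)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn)
    return {
        "n": int(len(df)),
        "n_correct": int(correct.sum()),
        "accuracy": float(correct.mean()),
        "f1": float(f1),
    }
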