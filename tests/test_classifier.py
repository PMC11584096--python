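import numpy as np
import pandas as pd
import pytest

from subspec.classifier import (
    GOF,
    LOF,
    NEUTRAL,
    MutationRecord,
    TuningGrid,
    build_feature_matrix,
    build_feature_row,
    casr_domain_map,
    conservation_score,
    evaluate,
    load_physchem_table,
    make_splits,
    normalize_features,
    predict_with_neutral_overlay,
    run_replications,
    scan_substitutions,
    score_table2_fixture,
    tune_and_train,
)
from subspec.io_core import Alignment
from subspec.synthetic import (
    PlantedMsaSpec,
    generate_mutation_dataset,
    generate_subfamily_msas,
    mutation_records,
    synthetic_domain_map,
)

from _oracles import auroc_oracle


@pytest.fixture(scope="module")
def planted_features():
    msa = generate_subfamily_msas(PlantedMsaSpec(seed=7))
    df = generate_mutation_dataset(msa, n=160, label_noise=0.0, seed=7)
    X = build_feature_matrix(mutation_records(df), msa.subfamily_alignments,
                             synthetic_domain_map(200))
    return msa, df, X


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def test_conservation_score_examples():
    aln = Alignment({"a": "AA", "b": "AA", "c": "AG", "d": "A-"}, "a")
    assert conservation_score(aln, 1, "A") == 1.0
    assert conservation_score(aln, 2, "G") == 0.25
    assert conservation_score(aln, 2, "W") == 0.0
    with pytest.raises(ValueError):
        conservation_score(aln, 3, "A")


def test_zimmerman_polarity_lookup_values():
    table = load_physchem_table()
    assert table.loc["H", "zimmerman_polarity"] == pytest.approx(51.600)
    assert table.loc["L", "zimmerman_polarity"] == pytest.approx(0.30)


def test_feature_row_deterministic_and_fixed_order():
    aln = Alignment({"a": "ACDEF", "b": "ACDEF"}, "a")
    alns = {"SF1": aln, "SF2": aln}
    rec = MutationRecord(2, "C", "W")
    domains = {i: "CRD" for i in range(1, 6)}
    r1 = build_feature_row(rec, alns, domains)
    r2 = build_feature_row(rec, alns, domains)
    assert r1.equals(r2)
    assert r1["cons_SF1_aa0"] == 1.0 and r1["cons_SF1_aa1"] == 0.0
    assert r1["domain_CRD"] == 1.0
    assert r1["blosum_aa0_C"] == 9.0  # BLOSUM62 diagonal for C


def test_feature_row_uncovered_position_flags_zero():
    long = Alignment({"a": "ACDEF", "b": "ACDEF"}, "a")
    short = Alignment({"x": "AC", "y": "AC"}, "x")
    rec = MutationRecord(4, "E", "K")
    row = build_feature_row(rec, {"SF1": long, "SF2": short}, {})
    assert row["cov_SF1"] == 1.0 and row["cov_SF2"] == 0.0
    assert row["cons_SF2_aa0"] == 0.0


def test_mutation_record_parsing_and_validation():
    rec = MutationRecord.parse("p.I857S")
    assert (rec.position, rec.aa0, rec.aa1) == (857, "I", "S")
    with pytest.raises(ValueError):
        MutationRecord(5, "A", "A")
    with pytest.raises(ValueError):
        MutationRecord.parse("857S")


def test_casr_domain_map_covers_reference_length():
    dm = casr_domain_map()
    assert dm[20] == "VFT-LB1"
    assert dm[700] == "TM3"
    assert dm[1078] == "cytoplasmic"
    assert len(dm) == 1078


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_normalize_zscore_oracle():
    train = pd.DataFrame({"f": [1.0, 2.0, 3.0], "domain_TM1": [1.0, 0.0, 0.0]})
    test = pd.DataFrame({"f": [2.0], "domain_TM1": [0.0]})
    strain, (stest,), mean, sd = normalize_features(train, test)
    assert np.allclose(strain["f"], [-1.224744871, 0.0, 1.224744871])
    assert stest["f"].iloc[0] == 0.0  # equals the training mean
    assert strain["domain_TM1"].tolist() == [1.0, 0.0, 0.0]  # one-hot untouched


def test_normalize_constant_column_zeroed(caplog):
    train = pd.DataFrame({"f": [5.0, 5.0, 5.0]})
    with caplog.at_level("WARNING"):
        strain, _, _, _ = normalize_features(train)
    assert (strain["f"] == 0.0).all()
    assert "zero-variance" in caplog.text


def test_leakage_guard_test_rows_never_change_training_stats():
    rng = np.random.default_rng(0)
    train = pd.DataFrame({"f": rng.normal(size=20)})
    test_a = pd.DataFrame({"f": rng.normal(size=5)})
    test_b = pd.DataFrame({"f": rng.normal(10.0, 5.0, size=5)})
    strain_a, _, mean_a, sd_a = normalize_features(train, test_a)
    strain_b, _, mean_b, sd_b = normalize_features(train, test_b)
    assert mean_a.equals(mean_b) and sd_a.equals(sd_b)
    assert strain_a.equals(strain_b)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def test_make_splits_stratified_and_deterministic():
    labels = np.array([GOF] * 25 + [LOF] * 75)
    plans = make_splits(labels, n_replications=3, seed=5)
    for plan in plans:
        test_labels = labels[plan.test_idx]
        assert abs((test_labels == GOF).sum() - 5) <= 1
        assert len(np.intersect1d(plan.train_idx, plan.test_idx)) == 0
        assert len(plan.folds) == 5
        for fit_idx, val_idx in plan.folds:
            assert set(val_idx) <= set(plan.train_idx)
            assert len(np.intersect1d(fit_idx, val_idx)) == 0
    again = make_splits(labels, n_replications=3, seed=5)
    for p, q in zip(plans, again):
        assert np.array_equal(p.train_idx, q.train_idx)
        assert np.array_equal(p.test_idx, q.test_idx)


def test_make_splits_requires_both_classes():
    with pytest.raises(ValueError):
        make_splits(np.array([LOF] * 50), 1, 0)


# ---------------------------------------------------------------------------
# Tuning and training
# ---------------------------------------------------------------------------

def test_tuning_follows_grid_order_and_is_deterministic(planted_features):
    _, df, X = planted_features
    y = df["label"].to_numpy()
    grid = TuningGrid(steps=(("learning_rate", (5e-4, 1e-3)), ("reg_lambda", (0.0, 1.0))))
    plan = make_splits(y, 1, seed=3)[0]
    m1 = tune_and_train(X, y, plan, grid)
    m2 = tune_and_train(X, y, plan, grid)
    assert [name for name, _, _ in m1.tuning_trace] == ["learning_rate", "reg_lambda"]
    assert m1.params == m2.params


def test_separable_data_trains_to_perfect_training_auroc(planted_features):
    _, df, X = planted_features  # noise-free planted labels are separable
    y = df["label"].to_numpy()
    plan = make_splits(y, 1, seed=1)[0]
    model = tune_and_train(X, y, plan, TuningGrid.fixed(learning_rate=0.3))
    X_train, _, _, _ = normalize_features(X.iloc[plan.train_idx])
    metrics = evaluate(y[plan.train_idx], model.predict_proba_gof(X_train))
    assert metrics["auroc"] == 1.0


def test_label_shuffle_gives_chance_level(planted_features):
    _, df, X = planted_features
    rng = np.random.default_rng(123)
    y_shuffled = rng.permutation(df["label"].to_numpy())
    metrics = run_replications(X, y_shuffled, n_replications=10,
                               grid=TuningGrid.fixed(), seed=9)
    assert metrics["test_auroc"].mean() == pytest.approx(0.5, abs=0.12)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def test_evaluate_matches_rank_oracle():
    rng = np.random.default_rng(2)
    for _ in range(500):
        n = int(rng.integers(6, 60))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        m = evaluate(np.where(y == 1, GOF, LOF), s)
        assert m["auroc"] == pytest.approx(auroc_oracle(y, s), abs=1e-12)


def test_evaluate_edge_cases():
    y = [GOF, GOF, LOF, LOF]
    assert evaluate(y, [0.9, 0.8, 0.2, 0.1])["auroc"] == 1.0
    m = evaluate(y, [0.9, 0.9, 0.9, 0.9])  # everything called GoF
    assert m["f1_lof"] == 0.0
    with pytest.raises(ValueError):
        evaluate([GOF, GOF], [0.5, 0.6])


# ---------------------------------------------------------------------------
# Neutral overlay
# ---------------------------------------------------------------------------

def test_neutral_overlay_rule(planted_features):
    msa, df, X = planted_features
    y = df["label"].to_numpy()
    plan = make_splits(y, 1, seed=1)[0]
    model = tune_and_train(X, y, plan, TuningGrid.fixed())
    casr_aln = msa.subfamily_alignments[msa.spec.subfamilies[0]]
    # a substitution to a residue present in the column is neutral
    col0 = casr_aln.column(0)
    ref_aa = casr_aln.reference_sequence[0]
    observed_alt = next((a for a in set(col0) if a not in (ref_aa, "-")), None)
    records = [MutationRecord(1, ref_aa, observed_alt or "W")]
    feats = build_feature_matrix(records, msa.subfamily_alignments,
                                 synthetic_domain_map(200))
    calls = predict_with_neutral_overlay(model, records, feats, casr_aln)
    if observed_alt is not None:
        assert calls == [NEUTRAL]
    else:
        assert calls[0] in (GOF, LOF)


def test_scan_substitutions_covers_19_per_position():
    aln = Alignment({"a": "ACD", "b": "ACD"}, "a")
    records = scan_substitutions(aln)
    assert len(records) == 3 * 19
    assert all(r.aa0 != r.aa1 for r in records)


# ---------------------------------------------------------------------------
# The packaged validation table
# ---------------------------------------------------------------------------

def test_table2_scoring_exact():
    result = score_table2_fixture()
    assert result["n"] == 22
    assert result["n_correct"] == 17
    assert result["accuracy"] == pytest.approx(17 / 22)
    assert result["f1"] == pytest.approx(24 / 29)


def test_table2_star_flags_match_correctness():
    from subspec.synthetic import table2_fixture

    df = table2_fixture()
    truth = np.where(df["cause"] == "hypercalcemia", "loss-of-function",
                     "gain-of-function")
    assert ((df["prediction"] == truth) == df["starred"]).all()
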