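import collections

import numpy as np
import pytest

from subspec.alphabet import AMINO_ACIDS, GAP, SYMBOLS
from subspec.hmm import (
    PRESETS,
    GroupingScheme,
    PositionRepresentatives,
    PositionTyping,
    WeightConstants,
    WeightedProfile,
    _type_one_position,
    assign_subfamily,
    assign_position_type,
    build_weighted_profile,
    column_frequencies,
    compute_position_weights,
    export_hmmer3,
    normalized_blosum,
    score_sequence,
    select_representatives,
)
from subspec.io_core import Alignment

from _oracles import position_type_oracle, weights_oracle


def _freq_row(**kwargs):
    row = np.zeros(len(SYMBOLS))
    for sym, f in kwargs.items():
        row[SYMBOLS.index(sym if sym != "gap" else GAP)] = f
    return row


# ---------------------------------------------------------------------------
# Frequencies and representatives
# ---------------------------------------------------------------------------

def test_column_frequencies():
    aln = Alignment({"a": "AA", "b": "AA", "c": "AG", "d": "A-"}, "a")
    f = column_frequencies(aln)
    assert f[0, SYMBOLS.index("A")] == 1.0
    assert f[1, SYMBOLS.index("A")] == 0.5
    assert f[1, SYMBOLS.index("G")] == 0.25
    assert f[1, SYMBOLS.index(GAP)] == 0.25
    assert np.allclose(f.sum(axis=1), 1.0)


def test_select_representatives_rules():
    scheme = GroupingScheme(("T",), ("C",), ("R1", "R2"))
    # target: most frequent symbol wins
    freqs = {
        "T": _freq_row(A=0.9, G=0.1)[None, :],
        "C": _freq_row(A=0.8, V=0.2)[None, :],
        # rest member 1 tops with A (matches target's rep)
        "R1": _freq_row(A=0.7, L=0.3)[None, :],
        "R2": _freq_row(V=0.95, A=0.05)[None, :],
    }
    reps = select_representatives(freqs, scheme)
    assert reps.r_t[0] == "A" and reps.s_t[0] == pytest.approx(0.9)
    assert reps.r_r[0] == "A" and reps.s_r[0] == pytest.approx(0.7)
    # no rest member tops with the target's rep: highest-top member wins,
    # score is the mean of member top frequencies
    freqs["R1"] = _freq_row(L=0.8, A=0.2)[None, :]
    reps = select_representatives(freqs, scheme)
    assert reps.r_r[0] == "V"
    assert reps.s_r[0] == pytest.approx((0.8 + 0.95) / 2)


def test_tie_break_alphabetical_and_gap_loses():
    aln = Alignment({"a": "A", "b": "C", "c": "-", "d": "-"}, "a")
    f = column_frequencies(aln)
    # A and C tie at 0.25 against gap 0.5 is not the case here: gap 0.5 wins
    from subspec.hmm import top_symbol

    sym, freq = top_symbol(f[0])
    assert sym == GAP and freq == 0.5
    aln2 = Alignment({"a": "A", "b": "C", "c": "A", "d": "C"}, "a")
    sym, _ = top_symbol(column_frequencies(aln2)[0])
    assert sym == "A"  # alphabetical tie-break
    aln3 = Alignment({"a": "A", "b": "-"}, "a")
    sym, _ = top_symbol(column_frequencies(aln3)[0])
    assert sym == "A"  # residue beats gap on ties


# ---------------------------------------------------------------------------
# Normalized BLOSUM
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ("W", "W", 1.0),
    ("L", "V", 0.25),
    ("L", "I", 0.5),
    ("L", "F", 0.0),
    ("L", "M", 0.5),
])
def test_normalized_blosum(a, b, expected):
    assert normalized_blosum(a, b) == pytest.approx(expected)


def test_normalized_blosum_diagonal_is_one():
    for a in AMINO_ACIDS:
        assert normalized_blosum(a, a) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Position typing
# ---------------------------------------------------------------------------

CASR = PRESETS["CaSR"]


@pytest.mark.parametrize("args,expected", [
    # shared target/closest representative: category 4, type II
    (("A", 0.9, "A", 0.8, "V", 0.7), (4, "II", 1 / 2.4)),
    # conserved and all-distinct: category 3, type I
    (("L", 0.99, "V", 0.85, "I", 0.9), (3, "I", 2.74)),
    # closest and rest both gap: category 1, type I
    (("A", 0.95, GAP, 0.9, GAP, 0.85), (1, "I", 2.70)),
    # below thr1 but BLOSUM-dissimilar representatives: type I
    (("L", 0.9, "F", 0.9, "M", 0.9), (3, "I", 2.70)),
])
def test_position_type_examples(args, expected):
    cat, ptype, score = _type_one_position(*args, CASR)
    assert (cat, ptype) == expected[:2]
    assert score == pytest.approx(expected[2])


def test_position_type_matches_oracle_bulk():
    rng = np.random.default_rng(7)
    consts_pool = list(PRESETS.values()) + [WeightConstants()]
    symbols = list(AMINO_ACIDS) + [GAP] * 6
    for _ in range(2000):
        r = [symbols[i] for i in rng.integers(len(symbols), size=3)]
        if rng.random() < 0.4:  # force equality patterns often
            r[int(rng.integers(3))] = r[int(rng.integers(3))]
        s = rng.uniform(0.05, 1.0, 3)
        consts = consts_pool[int(rng.integers(len(consts_pool)))]
        reps = PositionRepresentatives(
            np.array([r[0]], object), np.array([s[0]]),
            np.array([r[1]], object), np.array([s[1]]),
            np.array([r[2]], object), np.array([s[2]]),
        )
        typing = assign_position_type(reps, consts)
        cat, ptype, score = position_type_oracle(
            r[0], s[0], r[1], s[1], r[2], s[2],
            consts.thr1, consts.thr2, consts.thr_bls,
        )
        assert typing.category[0] == cat
        assert typing.ptype[0] == ptype
        assert typing.score[0] == pytest.approx(score, abs=1e-12)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def _typing(types, scores):
    return PositionTyping(np.zeros(len(types), int), np.array(types, object),
                          np.array(scores, float))


def test_weight_examples():
    consts = WeightConstants(c1=1.0, c4_mode="const", c4_const=0.2)
    t = _typing(["I", "I", "IV", "IV", "II", "II"], [2.0, 3.0, 2.5, 2.0, 0.5, 0.4])
    w = compute_position_weights(t, consts)
    assert w[:2] == pytest.approx([1.0, 1.5])
    # c2 = mean(type I weights) = 1.25
    assert w[2:4] == pytest.approx([1.25, 1.0])
    assert w[4:] == pytest.approx([0.2, 0.16])


def test_weight_gprc6a_doubles_type1():
    consts = PRESETS["GPRC6A"]
    t = _typing(["I", "I", "IV", "II"], [2.0, 3.0, 2.5, 0.5])
    w = compute_position_weights(t, consts)
    assert w[:2] == pytest.approx([2.0, 3.0])


def test_weight_requires_type1():
    with pytest.raises(ValueError, match="type I"):
        compute_position_weights(_typing(["II", "IV"], [0.5, 2.0]), WeightConstants())


def test_weight_c3_fallback_without_type4(caplog):
    consts = PRESETS["GPRC6A"]  # c3 derives from type IV
    t = _typing(["I", "III", "II"], [2.0, 1.5, 0.5])
    with caplog.at_level("WARNING"):
        w = compute_position_weights(t, consts)
    assert w[1] == pytest.approx(0.5)  # fallback cap
    assert "c3" in caplog.text


def test_weight_matches_oracle_bulk():
    rng = np.random.default_rng(11)
    consts_pool = list(PRESETS.values())
    for _ in range(1000):
        n = int(rng.integers(4, 40))
        types = [("I", "II", "III", "IV")[i] for i in rng.integers(4, size=n)]
        types[int(rng.integers(n))] = "I"
        scores = rng.uniform(0.1, 3.0, n)
        consts = consts_pool[int(rng.integers(len(consts_pool)))]
        w = compute_position_weights(_typing(types, scores), consts)
        expect = weights_oracle(types, scores, consts.c1, consts.c3_mode,
                                consts.c3_const, consts.c4_mode, consts.c4_const,
                                consts.double_type1)
        assert np.allclose(w, expect, atol=1e-12)


def test_weight_monotone_in_score_within_type():
    t = _typing(["I", "I", "I", "IV", "IV", "II", "II", "III", "III"],
                [1.0, 2.0, 3.0, 1.0, 2.0, 0.3, 0.6, 1.0, 2.0])
    w = compute_position_weights(t, PRESETS["CaSR"])
    for idx in ([0, 1, 2], [3, 4], [5, 6], [7, 8]):
        assert all(np.diff(w[idx]) > 0)


# ---------------------------------------------------------------------------
# Profiles and scoring
# ---------------------------------------------------------------------------

@pytest.fixture()
def toy_profile():
    rows = {f"s{i}": "ACDEFGHIKL" for i in range(4)}
    rows["s4"] = "ACDEFGHIKV"
    return build_weighted_profile(Alignment(rows, "s0"), np.ones(10), "toy")


def test_reweight_identity_at_weight_one(toy_profile):
    assert np.allclose(toy_profile.reweighted, toy_profile.baseline)


def test_weight_scales_log_odds_contribution(toy_profile):
    cons = toy_profile.consensus
    base = score_sequence(toy_profile, cons)
    doubled = WeightedProfile("x", toy_profile.baseline,
                              np.full(10, 2.0), toy_profile.column_map)
    zeroed = WeightedProfile("x", toy_profile.baseline,
                             np.zeros(10), toy_profile.column_map)
    assert score_sequence(doubled, cons) == pytest.approx(2 * base)
    assert score_sequence(zeroed, cons) == 0.0


def test_consensus_maximal_among_single_substitutions(toy_profile):
    cons = toy_profile.consensus
    best = score_sequence(toy_profile, cons)
    for i in range(len(cons)):
        for a in AMINO_ACIDS:
            if a != cons[i]:
                variant = cons[:i] + a + cons[i + 1:]
                assert score_sequence(toy_profile, variant) <= best


def test_shuffled_sequences_score_below_consensus(toy_profile):
    rng = np.random.default_rng(3)
    cons = toy_profile.consensus
    best = score_sequence(toy_profile, cons)
    below = 0
    for _ in range(100):
        shuffled = "".join(rng.permutation(list(cons)))
        if score_sequence(toy_profile, shuffled) < best:
            below += 1
    assert below == 100


def test_score_sequence_rejects_empty(toy_profile):
    with pytest.raises(ValueError):
        score_sequence(toy_profile, "")


def test_export_hmmer3_roundtrip(tmp_path, toy_profile):
    import pyhmmer

    path = tmp_path / "toy.hmm"
    export_hmmer3(toy_profile, path)
    with pyhmmer.plan7.HMMFile(str(path)) as hf:
        hmm = next(iter(hf))
    assert hmm.M == toy_profile.n_columns
    em = np.asarray(hmm.match_emissions)[1:]
    assert np.allclose(em, toy_profile.reweighted, atol=1e-4)


# ---------------------------------------------------------------------------
# Separation on the planted fixture
# ---------------------------------------------------------------------------

def test_weighting_widens_separation_margin(msa_result, profile_builds, holdout_scores):
    """The weighted profile separates target from closest-group sequences by
    a strictly wider margin than the unweighted profile.

    Margins are compared per unit of total column weight: a global rescaling
    of all weights rescales every score, so the raw bit margin is not a
    meaningful basis for comparison between the two profiles.
    """
    target = msa_result.spec.subfamilies[0]
    closest = msa_result.scheme.closest[0]
    weight_sum = {
        "weighted": float(profile_builds[target].weights.sum()),
        "unweighted": float(profile_builds[target].profile.n_columns),
    }

    def margin(kind):
        own = [s[target] for (o, _), s in holdout_scores[kind].items() if o == target]
        other = [s[target] for (o, _), s in holdout_scores[kind].items() if o == closest]
        return (min(own) - max(other)) / weight_sum[kind]

    assert margin("weighted") > margin("unweighted")


# ---------------------------------------------------------------------------
# Subfamily assignment rule
# ---------------------------------------------------------------------------

def test_assign_subfamily_three_conditions():
    ranges = {"CaSR": {"Mammalia", "Aves"}, "GPRC6A": {"Mammalia"}}
    hits = {"CaSR": (100.0, 1e-50), "GPRC6A": (50.0, 1e-20)}
    assert assign_subfamily(hits, "Mammalia", ranges) == "CaSR"
    # score and e-value disagree
    hits = {"CaSR": (100.0, 1e-20), "GPRC6A": (50.0, 1e-50)}
    assert assign_subfamily(hits, "Mammalia", ranges) is None
    # taxon outside the subfamily's clade
    hits = {"CaSR": (100.0, 1e-50), "GPRC6A": (50.0, 1e-20)}
    assert assign_subfamily(hits, "Teleostei", ranges) is None


def test_grouping_scheme_validation():
    with pytest.raises(ValueError):
        GroupingScheme(("A",), ("A",), ("B",))
    with pytest.raises(ValueError):
        GroupingScheme(("A",), (), ("B",))
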