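"""Delta-bitscore, HAC calling, and the degradation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nichesig import (
    BitscoreMatrix,
    call_hacs,
    generate_proteome_pair,
    hac_count_anova,
    median_benchmark_dbs,
    pairwise_dbs,
    wilcoxon_skewness_test,
)
from nichesig.errors import (
    DegenerateDataError,
    EmptyComparisonError,
    InsufficientDataError,
    ParameterError,
)


# --------------------------------------------------------------- pairwise


def test_pairwise_dbs_is_ref_minus_var():
    ref = pd.Series({"g": 100.0})
    var = pd.Series({"g": 90.0})
    table = pairwise_dbs(ref, var)
    assert table.data.loc["g", "dbs"] == 10.0


def test_identical_vectors_give_zero_dbs():
    v = pd.Series({"a": 10.0, "b": 55.5})
    assert (pairwise_dbs(v, v).dbs == 0.0).all()


def test_absent_genes_excluded_by_default_included_as_zero_by_flag():
    ref = pd.Series({"a": 10.0, "b": np.nan, "c": 30.0})
    var = pd.Series({"a": 8.0, "b": 5.0, "d": 1.0})
    table = pairwise_dbs(ref, var)
    assert table.genes == ["a"]
    table0 = pairwise_dbs(ref, var, absent_as_zero=True)
    assert table0.data.loc["b", "dbs"] == -5.0


def test_disjoint_gene_sets_raise():
    with pytest.raises(EmptyComparisonError):
        pairwise_dbs(pd.Series({"a": 1.0}), pd.Series({"b": 2.0}))


@settings(deadline=None, max_examples=25)
@given(
    st.lists(
        st.floats(min_value=-500, max_value=500, allow_nan=False),
        min_size=1,
        max_size=30,
    ),
    st.lists(
        st.floats(min_value=-500, max_value=500, allow_nan=False),
        min_size=1,
        max_size=30,
    ),
)
def test_pairwise_antisymmetry(xs, ys):
    n = min(len(xs), len(ys))
    genes = [f"g{i}" for i in range(n)]
    a = pd.Series(xs[:n], index=genes)
    b = pd.Series(ys[:n], index=genes)
    ab = pairwise_dbs(a, b).dbs
    ba = pairwise_dbs(b, a).dbs
    assert (ab == -ba).all()


# --------------------------------------------------------- median benchmark


def test_median_benchmark_three_strains():
    frame = pd.DataFrame(
        {"s1": [10.0], "s2": [20.0], "s3": [30.0]}, index=["g"]
    )
    tables = median_benchmark_dbs(BitscoreMatrix(frame))
    assert tables["s1"].data.loc["g", "dbs"] == 10.0
    assert tables["s2"].data.loc["g", "dbs"] == 0.0
    assert tables["s3"].data.loc["g", "dbs"] == -10.0


def test_median_benchmark_identical_strains_all_zero():
    frame = pd.DataFrame({s: [7.0, 3.0] for s in "abc"}, index=["g1", "g2"])
    tables = median_benchmark_dbs(BitscoreMatrix(frame))
    for t in tables.values():
        assert (t.dbs == 0.0).all()


def test_median_property_and_incomplete_genes_dropped():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        rng.normal(100, 10, size=(50, 5)),
        index=[f"g{i}" for i in range(50)],
        columns=list("abcde"),
    )
    frame.iloc[0, 0] = np.nan
    tables = median_benchmark_dbs(BitscoreMatrix(frame))
    assert "g0" not in tables["a"].genes
    # per gene, at most half the strains can lie strictly below the median
    positive = sum((t.dbs > 0).astype(int) for t in tables.values())
    assert (positive <= 5 // 2).all()


def test_median_benchmark_location_invariance():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(
        rng.normal(100, 5, size=(20, 4)),
        index=[f"g{i}" for i in range(20)],
        columns=list("abcd"),
    )
    offset = pd.Series(rng.uniform(-50, 50, 20), index=frame.index)
    shifted = frame.add(offset, axis=0)
    t1 = median_benchmark_dbs(BitscoreMatrix(frame))
    t2 = median_benchmark_dbs(BitscoreMatrix(shifted))
    for s in "abcd":
        pd.testing.assert_series_equal(t1[s].dbs, t2[s].dbs, atol=1e-9, rtol=0)


def test_median_benchmark_needs_three_strains():
    frame = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
    with pytest.raises(ParameterError):
        median_benchmark_dbs(BitscoreMatrix(frame))


# ------------------------------------------------------------------- HACs


def test_null_hac_fraction_close_to_tail_fraction():
    rng = np.random.default_rng(123)
    fracs = [
        call_hacs(rng.standard_normal(10_000)).fraction for _ in range(20)
    ]
    assert np.mean(fracs) == pytest.approx(0.025, abs=0.005)


def test_all_zero_dbs_yields_no_hacs():
    calls = call_hacs(np.zeros(100))
    assert calls.hacs == set()
    assert calls.cutoff == 0.0
    assert calls.least_dispersed_tail == "negative"


def test_too_few_records_rejected():
    with pytest.raises(InsufficientDataError):
        call_hacs(np.random.default_rng(0).normal(size=20))


def test_invalid_tail_fraction_rejected():
    with pytest.raises(ParameterError):
        call_hacs(np.zeros(100), tail_fraction=0.6)


def test_hacs_fall_on_the_dispersed_side():
    # right-skewed: positive tail carries signal, negative tail calibrates
    rng = np.random.default_rng(7)
    values = np.concatenate([rng.normal(0, 1, 2000), rng.normal(8, 1, 100)])
    table = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
    calls = call_hacs(table)
    assert calls.least_dispersed_tail == "negative"
    assert all(table[g] > calls.cutoff for g in calls.hacs)


def test_two_sided_calls_superset_of_one_sided():
    rng = np.random.default_rng(8)
    values = pd.Series(
        rng.standard_normal(5000), index=[f"g{i}" for i in range(5000)]
    )
    one = call_hacs(values)
    two = call_hacs(values, two_sided=True)
    assert one.hacs <= two.hacs


def test_strongly_degraded_genes_all_recovered():
    """At a 10-SD planted shift the HAC set contains all degraded genes."""
    for seed in range(5):
        ref, var, truth = generate_proteome_pair(1000, 25, shift=50.0, seed=seed)
        calls = call_hacs(pairwise_dbs(ref, var))
        assert truth <= calls.hacs


def test_hac_recall_monotone_in_shift():
    shifts = [0.0, 10.0, 25.0, 50.0]
    recalls = []
    for shift in shifts:
        per_seed = []
        for seed in range(5):
            ref, var, truth = generate_proteome_pair(
                1000, 25, shift=shift, seed=seed
            )
            calls = call_hacs(pairwise_dbs(ref, var))
            per_seed.append(len(calls.hacs & truth) / 25)
        recalls.append(np.mean(per_seed))
    assert all(a <= b + 1e-12 for a, b in zip(recalls, recalls[1:]))


# --------------------------------------------------------------- Wilcoxon


def brute_force_signed_rank_p(values: np.ndarray) -> float:
    """Exhaustive 2^n enumeration of the signed-rank null (tie-free input)."""
    values = values[values != 0]
    ranks = stats.rankdata(np.abs(values))
    w_obs = ranks[values > 0].sum()
    ws = np.array(
        [
            ranks[np.array(signs, dtype=bool)].sum()
            for signs in itertools.product([0, 1], repeat=len(values))
        ]
    )
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


def test_perfectly_symmetric_dbs_gives_p_one():
    assert wilcoxon_skewness_test(np.array([1, -1, 2, -2, 3, -3], float)) == 1.0


def test_all_positive_small_sample_matches_enumeration():
    values = np.arange(1.0, 7.0)
    assert wilcoxon_skewness_test(values) == pytest.approx(2 / 64)
    assert brute_force_signed_rank_p(values) == pytest.approx(2 / 64)


@pytest.mark.parametrize("n,seed", [(8, 0), (10, 1), (12, 2), (12, 3)])
def test_matches_exhaustive_sign_enumeration(n, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(0.5, 1.0, n)
    assert len(np.unique(np.abs(values))) == n  # tie-free draw
    assert wilcoxon_skewness_test(values) == pytest.approx(
        brute_force_signed_rank_p(values), abs=1e-12
    )


def test_mirrored_input_gives_identical_p():
    rng = np.random.default_rng(4)
    values = rng.normal(1, 2, 15)
    assert wilcoxon_skewness_test(values) == pytest.approx(
        wilcoxon_skewness_test(-values)
    )


def test_degenerate_and_small_inputs_rejected():
    with pytest.raises(DegenerateDataError):
        wilcoxon_skewness_test(np.zeros(10))
    with pytest.raises(InsufficientDataError):
        wilcoxon_skewness_test(np.array([1.0, -2.0, 3.0]))


# ------------------------------------------------------------------ ANOVA


def test_identical_groups_f_zero_p_one():
    f, p = hac_count_anova({"env": [5, 5, 5], "gut": [5, 5, 5]})
    assert f == 0.0
    assert p == 1.0


def test_two_group_anova_matches_hand_computation():
    # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5; SSW = 2 + 2 = 4; F = 13.5/(4/4)
    f, p = hac_count_anova({"env": [1, 2, 3], "gut": [4, 5, 6]})
    assert f == pytest.approx(13.5)
    assert p == pytest.approx(0.0213116411, abs=1e-8)


def test_f_equals_squared_t():
    a, b = [3, 8, 5, 9], [12, 15, 11, 14, 13]
    f, p_f = hac_count_anova({"env": a, "gut": b})
    t, p_t = stats.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t**2)
    assert p_f == pytest.approx(p_t)


def test_location_invariance_of_f():
    f1, _ = hac_count_anova({"env": [1, 2, 3], "gut": [4, 5, 6]})
    f2, _ = hac_count_anova({"env": [101, 102, 103], "gut": [104, 105, 106]})
    assert f1 == pytest.approx(f2)


def test_group_count_and_size_validation():
    with pytest.raises(ParameterError):
        hac_count_anova({"env": [1, 2]})
    with pytest.raises(ParameterError):
        hac_count_anova({"env": [1, 2], "gut": [3]})
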