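"""Random-forest training, iterative feature selection, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichesig import (
    ENVIRONMENT,
    GASTROINTESTINAL,
    BitscoreMatrix,
    RFConfig,
    SyntheticSpec,
    generate_dataset,
    heatmap_matrix,
    iterative_feature_selection,
    predict_source,
    train_rf,
)
from nichesig.classifier import STATUS_CONVERGED, imputation_values
from nichesig.errors import ParameterError


def make_dataset(**kw):
    defaults = dict(
        n_env=4, n_gut=5, n_genes=100, n_informative=10, effect_size=3.0,
        missing_rate=0.0, seed=0,
    )
    defaults.update(kw)
    return generate_dataset(SyntheticSpec(**defaults))


# ------------------------------------------------------------------ config


@pytest.mark.parametrize(
    "kw",
    [
        dict(ntree=0),
        dict(vote_threshold=0.0),
        dict(vote_threshold=1.0),
        dict(max_iterations=0),
        dict(importance="magic"),
        dict(prune_rule="drop_some"),
        dict(impute="zeros"),
    ],
)
def test_bad_config_rejected(kw):
    with pytest.raises(ParameterError):
        RFConfig(**kw)


@pytest.mark.parametrize(
    "mtry,n,expected",
    [
        ("n/10", 6709, 670),
        ("n/10", 5, 1),  # floor then min 1
        ("n", 40, 40),
        ("sqrt", 100, 10),
        (7, 100, 7),
        (500, 100, 100),  # clipped to feature count
    ],
)
def test_mtry_resolution(mtry, n, expected):
    assert RFConfig(mtry=mtry).resolve_mtry(n) == expected


# ---------------------------------------------------------------- train_rf


def test_vote_proportions_sum_to_one_and_accuracy_in_range():
    ds = make_dataset()
    model = train_rf(ds.matrix, ds.labels, RFConfig(ntree=100, seed=1))
    sums = model.oob_votes.sum(axis=1)
    assert np.allclose(sums, 1.0)
    assert 0.0 <= model.oob_accuracy <= 1.0
    assert list(model.oob_votes.columns) == [ENVIRONMENT, GASTROINTESTINAL]


def test_single_class_labels_rejected():
    ds = make_dataset()
    labels = pd.Series(GASTROINTESTINAL, index=ds.labels.index)
    with pytest.raises(ParameterError, match="class"):
        train_rf(ds.matrix, labels, RFConfig(ntree=10))


def test_empty_predictor_set_rejected():
    ds = make_dataset()
    with pytest.raises(ParameterError, match="empty predictor"):
        train_rf(ds.matrix, ds.labels, RFConfig(ntree=10), genes=[])


def test_dominant_gene_ranks_top_by_importance():
    """A single 10-SD habitat gene among 50 noise genes dominates VI.

    With all features in play at each split (mtry = n) the planted gene is
    the only one whose out-of-bag permutation consistently costs accuracy.
    """
    ranks = []
    for seed in range(5):
        ds = make_dataset(n_genes=51, n_informative=1, effect_size=10.0, seed=seed)
        model = train_rf(
            ds.matrix, ds.labels, RFConfig(ntree=500, mtry="n", seed=seed)
        )
        (gene,) = ds.informative_genes()
        ranks.append(int((model.importance > model.importance[gene]).sum()) + 1)
    assert all(r <= 3 for r in ranks)
    assert sum(r == 1 for r in ranks) >= 3


def test_training_is_deterministic_given_seed():
    ds = make_dataset(missing_rate=0.05)
    cfg = RFConfig(ntree=150, seed=42)
    m1 = train_rf(ds.matrix, ds.labels, cfg)
    m2 = train_rf(ds.matrix, ds.labels, cfg)
    pd.testing.assert_series_equal(m1.importance, m2.importance)
    pd.testing.assert_frame_equal(m1.oob_votes, m2.oob_votes)
    assert m1.oob_accuracy == m2.oob_accuracy


def test_all_noise_accuracy_near_chance_over_seeds():
    """Without planted signal, single-forest OOB accuracy is not inflated."""
    accs = [
        train_rf(
            make_dataset(n_informative=0, seed=s).matrix,
            make_dataset(n_informative=0, seed=s).labels,
            RFConfig(ntree=100, seed=s),
        ).oob_accuracy
        for s in range(15)
    ]
    # chance for the 5/9 majority class is ~0.56; demand the mean not exceed
    # a generous band around it
    assert 0.2 <= np.mean(accs) <= 0.8


# ------------------------------------------------------------- imputation


def test_min_minus_sd_imputation_reads_absence_as_degradation():
    frame = pd.DataFrame(
        {"a": [10.0, 5.0], "b": [12.0, np.nan], "c": [14.0, 7.0]},
        index=["g1", "g2"],
    )
    fills = imputation_values(BitscoreMatrix(frame), "min_minus_sd")
    g2 = np.array([5.0, 7.0])
    assert fills["g2"] == pytest.approx(g2.min() - g2.std(ddof=1))
    med = imputation_values(BitscoreMatrix(frame), "median")
    assert med["g2"] == pytest.approx(6.0)


# -------------------------------------------------------------- selection


def test_selection_converges_and_enriches_planted_genes():
    ds = make_dataset(n_genes=600, n_informative=30, missing_rate=0.02, seed=1)
    trace = iterative_feature_selection(
        ds.matrix, ds.labels, RFConfig(ntree=400, seed=1)
    )
    assert trace.status == STATUS_CONVERGED
    assert trace.terminal.oob_accuracy == 1.0
    counts = trace.predictor_counts()
    assert all(a > b for a, b in zip(counts, counts[1:]))
    terminal = set(trace.terminal.genes)
    planted = set(ds.informative_genes())
    hits = len(terminal & planted)
    p = stats.binomtest(hits, len(terminal), 30 / 600, alternative="greater").pvalue
    assert p < 1e-6


def test_trace_votes_normalised_every_iteration():
    ds = make_dataset(seed=2)
    trace = iterative_feature_selection(
        ds.matrix, ds.labels, RFConfig(ntree=80, seed=2, max_iterations=5)
    )
    for it in trace.iterations:
        assert np.allclose(it.oob_votes.sum(axis=1), 1.0)
        assert 0.0 <= it.oob_accuracy <= 1.0


def test_selection_trace_is_reproducible():
    ds = make_dataset(seed=3)
    cfg = RFConfig(ntree=100, seed=3, max_iterations=6)
    t1 = iterative_feature_selection(ds.matrix, ds.labels, cfg)
    t2 = iterative_feature_selection(ds.matrix, ds.labels, cfg)
    assert t1.predictor_counts() == t2.predictor_counts()
    assert [i.oob_accuracy for i in t1.iterations] == [
        i.oob_accuracy for i in t2.iterations
    ]
    pd.testing.assert_series_equal(t1.terminal.importance, t2.terminal.importance)


def test_all_noise_trace_status_reported_honestly():
    """Whatever the outcome on pure noise, the trace must say what happened."""
    ds = make_dataset(n_genes=300, n_informative=0, seed=11)
    trace = iterative_feature_selection(
        ds.matrix, ds.labels, RFConfig(ntree=60, seed=11, max_iterations=4)
    )
    if trace.converged:
        assert trace.terminal.oob_accuracy == 1.0
    else:
        assert trace.terminal.oob_accuracy < 1.0
    counts = trace.predictor_counts()
    assert all(a > b for a, b in zip(counts, counts[1:]))


def test_trace_json_round_trip(tmp_path):
    import json

    ds = make_dataset(seed=4)
    trace = iterative_feature_selection(
        ds.matrix, ds.labels, RFConfig(ntree=50, seed=4, max_iterations=3)
    )
    path = tmp_path / "trace.json"
    trace.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["status"] == trace.status
    assert len(payload["iterations"]) == len(trace.iterations)
    assert payload["iterations"][0]["n_predictors"] == 100


# -------------------------------------------------------------- prediction


def test_training_strains_predicted_correctly_after_convergence():
    ds = make_dataset(n_genes=200, n_informative=20, effect_size=5.0, seed=5)
    trace = iterative_feature_selection(
        ds.matrix, ds.labels, RFConfig(ntree=300, seed=5)
    )
    assert trace.converged
    preds = predict_source(trace, ds.matrix)
    for r in preds:
        assert r.vote_env + r.vote_gut == pytest.approx(1.0)
        assert r.call == ds.labels[r.strain]


def test_midpoint_strain_votes_near_half():
    ds = make_dataset(n_genes=100, n_informative=100, effect_size=4.0, seed=6)
    model = train_rf(ds.matrix, ds.labels, RFConfig(ntree=500, seed=6))
    sc = ds.matrix.scores
    env = sc[[s for s in sc.columns if ds.labels[s] == ENVIRONMENT]].mean(axis=1)
    gut = sc[[s for s in sc.columns if ds.labels[s] == GASTROINTESTINAL]].mean(axis=1)
    mid = BitscoreMatrix(pd.DataFrame({"MID": (env + gut) / 2}))
    (r,) = predict_source(model, mid)
    assert 0.25 <= r.vote_gut <= 0.75


def test_missing_predictor_gene_is_imputed_and_flagged():
    ds = make_dataset(n_genes=60, n_informative=10, effect_size=5.0, seed=7)
    model = train_rf(ds.matrix, ds.labels, RFConfig(ntree=100, seed=7))
    new = BitscoreMatrix(ds.matrix.scores.iloc[1:][["ENV01"]].copy())
    (r,) = predict_source(model, new)
    dropped = ds.matrix.genes[0]
    assert dropped in r.fully_missing_genes
    assert r.vote_env + r.vote_gut == pytest.approx(1.0)


# ----------------------------------------------------------------- heatmap


def test_heatmap_rows_centered_and_unit_variance(tiny_matrix):
    scaled = heatmap_matrix(tiny_matrix, tiny_matrix.genes)
    assert np.allclose(scaled.mean(axis=1), 0.0, atol=1e-12)
    sds = scaled.std(axis=1, ddof=1)
    assert np.allclose(sds[sds > 0], 1.0)
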