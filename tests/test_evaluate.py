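import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crowdgp.evaluate import (
    annotator_rank_analysis,
    compare_models_significance,
    regression_metrics,
    run_benchmark,
    stratified_split,
    uniform_split,
)
from crowdgp.baselines import fit_sparse_gp, gpr_avg_fit, gpr_gt_fit
from crowdgp.model import TrainingConfig
from crowdgp.simulate import make_synthetic_task

FAST = TrainingConfig(n_inducing=15, batch_size=64, max_steps=60, seed=0)


def test_regression_metrics_handchecked():
    y = np.array([1.0, 2.0, 3.0])
    p = np.array([1.0, 2.5, 2.0])
    m = regression_metrics(y, p)
    assert m.mse == pytest.approx((0 + 0.25 + 1.0) / 3)
    assert m.mae == pytest.approx((0 + 0.5 + 1.0) / 3)
    assert m.mape == pytest.approx(100 * (0 + 0.5 / 2 + 1.0 / 3) / 3, rel=1e-5)
    ss_tot = np.sum((y - 2.0) ** 2)
    assert m.r2 == pytest.approx(1.0 - 1.25 / ss_tot)


def test_regression_metrics_perfect_and_degenerate():
    y = np.array([1.0, 2.0, 4.0])
    m = regression_metrics(y, y)
    assert m.mse == 0.0 and m.r2 == pytest.approx(1.0)
    m2 = regression_metrics(np.array([3.0, 3.0]), np.array([1.0, 5.0]))
    assert np.isnan(m2.r2)
    with pytest.raises(ValueError):
        regression_metrics(np.array([1.0]), np.array([1.0]))


def test_regression_metrics_match_sklearn(rng):
    from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

    y = rng.normal(size=40) + 3.0
    p = y + rng.normal(0, 0.3, 40)
    m = regression_metrics(y, p)
    assert m.mse == pytest.approx(mean_squared_error(y, p), rel=1e-12)
    assert m.mae == pytest.approx(mean_absolute_error(y, p), rel=1e-12)
    assert m.r2 == pytest.approx(r2_score(y, p), rel=1e-12)


def test_stratified_split_preserves_strata(rng):
    clusters = np.repeat([0, 1, 2, 3], [40, 30, 20, 10])
    tr, te = stratified_split(clusters, 0.7, rng)
    assert np.intersect1d(tr, te).size == 0
    assert tr.size + te.size == 100
    for c, n in zip(range(4), [40, 30, 20, 10]):
        n_tr = np.sum(clusters[tr] == c)
        assert n_tr == int(round(0.7 * n))


def test_stratified_split_small_stratum_warns(rng):
    clusters = np.array([0] * 10 + [1])
    with pytest.warns(UserWarning, match="smaller than 2"):
        tr, te = stratified_split(clusters, 0.7, rng)
    assert tr.size + te.size == 11


def test_uniform_split_partition(rng):
    tr, te = uniform_split(20, 0.7, rng)
    assert tr.size == 14 and te.size == 6
    assert np.intersect1d(tr, te).size == 0


def test_baseline_gpr_recovers_smooth_function(rng):
    X = rng.uniform(-3, 3, size=(120, 1))
    y = np.sin(X[:, 0]) + rng.normal(0, 0.1, 120)
    reg = fit_sparse_gp(X, y, TrainingConfig(n_inducing=20, batch_size=120,
                                             max_steps=600, seed=0))
    Xq = np.linspace(-2.5, 2.5, 50)[:, None]
    mean, var = reg.predict(Xq)
    assert np.mean((mean - np.sin(Xq[:, 0])) ** 2) < 0.02
    assert np.all(var >= 0)
    _, var_n = reg.predict(Xq, include_noise=True)
    assert np.all(var_n > var)


def test_gpr_avg_excludes_unlabeled_rows_with_warning():
    task = make_synthetic_task(60, C=4, seed=0)
    ds = task.dataset()
    ds.labels[0, :] = np.nan
    ds.observed_mask[0, :] = False
    with pytest.warns(UserWarning, match="excluding 1"):
        gpr_avg_fit(ds, FAST)


def test_gpr_gt_requires_ground_truth():
    task = make_synthetic_task(60, C=4, seed=0)
    with pytest.raises(ValueError, match="ground truth"):
        gpr_gt_fit(task.dataset(), FAST)


def test_run_benchmark_shape_and_determinism():
    task = make_synthetic_task(120, C=4, seed=3)
    rep1 = run_benchmark(task, ["gpr-avg", "gpr-gt"], repeats=5, cfg=FAST, seed=7)
    rep2 = run_benchmark(task, ["gpr-avg", "gpr-gt"], repeats=5, cfg=FAST, seed=7)
    assert len(rep1.metrics) == 10
    pd.testing.assert_frame_equal(rep1.metrics, rep2.metrics)
    table = rep1.score_table("r2")
    assert table.shape == (5, 2)
    agg = rep1.aggregate()
    assert ("mse", "mean") in agg.columns
    with pytest.raises(ValueError):
        run_benchmark(task, [], repeats=5)


def test_significance_against_scipy_direct(rng):
    a = rng.normal(0.8, 0.05, 15)
    b = a - np.abs(rng.normal(0.1, 0.02, 15))
    scores = pd.DataFrame({"ref": a, "worse": b})
    out = compare_models_significance(scores, "ref")
    # two groups: omnibus falls back to the exact sign test
    fr = out[out.comparison == "friedman"].iloc[0]
    assert fr.statistic == 15.0  # all differences positive
    assert fr.p_raw == pytest.approx(stats.binomtest(15, 15, 0.5).pvalue)
    w = out[out.comparison == "ref vs worse"].iloc[0]
    ws, wp = stats.wilcoxon(a, b, method="exact")
    assert w.statistic == pytest.approx(ws)
    assert w.p_corrected == pytest.approx(min(1.0, wp))  # one comparison
    assert w.p_corrected < 0.01  # clearly separated samples


def test_significance_friedman_three_methods(rng):
    a = rng.normal(0.8, 0.05, 12)
    b = a - np.abs(rng.normal(0.1, 0.02, 12))
    c = a + rng.normal(0.0, 0.03, 12)
    scores = pd.DataFrame({"ref": a, "worse": b, "peer": c})
    out = compare_models_significance(scores, "ref")
    fr = out[out.comparison == "friedman"].iloc[0]
    fs, fp = stats.friedmanchisquare(a, b, c)
    assert fr.statistic == pytest.approx(fs)
    assert fr.p_raw == pytest.approx(fp)
    # Bonferroni over 2 comparisons
    w = out[out.comparison == "ref vs worse"].iloc[0]
    assert w.p_corrected == pytest.approx(min(1.0, w.p_raw * 2))


def test_significance_bonferroni_and_degenerate(rng):
    a = rng.normal(size=10)
    scores = pd.DataFrame({"ref": a, "same": a.copy(), "other": a + 0.2})
    out = compare_models_significance(scores, "ref")
    deg = out[out.comparison == "ref vs same"].iloc[0]
    assert bool(deg.degenerate) and np.isnan(deg.p_raw)
    oth = out[out.comparison == "ref vs other"].iloc[0]
    assert oth.p_corrected == pytest.approx(min(1.0, oth.p_raw * 2))
    with pytest.raises(ValueError):
        compare_models_significance(scores.iloc[:3], "ref")
    with pytest.raises(ValueError):
        compare_models_significance(scores, "nope")


def test_annotator_rank_analysis_handchecked():
    trust = pd.DataFrame(
        {"acidity": [0.9, 0.5, 0.2], "bitterness": [0.8, 0.3, 0.6]},
        index=["expert", "mid", "weak"])
    ranks, mean_ranks, fr_stat, fr_p = annotator_rank_analysis(trust)
    assert ranks.loc["expert"].tolist() == [1.0, 1.0]
    assert ranks.loc["mid", "acidity"] == 2.0
    assert ranks.loc["weak", "bitterness"] == 2.0
    assert mean_ranks["expert"] == 1.0
    assert 0.0 <= fr_p <= 1.0


def test_annotator_rank_analysis_drops_nan_attributes():
    trust = pd.DataFrame(
        {"a": [0.9, 0.5], "b": [np.nan, 0.3], "c": [0.7, 0.2]},
        index=["x", "y"])
    with pytest.warns(UserWarning, match="dropping"):
        ranks, _, _, _ = annotator_rank_analysis(trust)
    assert list(ranks.columns) == ["a", "c"]
    with pytest.raises(ValueError):
        annotator_rank_analysis(pd.DataFrame({"a": [0.9, np.nan], "b": [1.0, np.nan]},
                                             index=["x", "y"]))


def test_crowd_model_beats_naive_average_on_heteroscedastic_task():
    """One split, moderate budget: chained crowd model should use annotator
    structure and beat the naive per-sample average baseline."""
    task = make_synthetic_task(250, C=4, seed=11)
    cfg = TrainingConfig(n_inducing=30, batch_size=125, max_steps=250, seed=1)
    rep = run_benchmark(task, ["crowd-ccgp", "gpr-avg"], repeats=2, cfg=cfg, seed=5)
    agg = rep.aggregate()
    assert agg.loc["crowd-ccgp", ("mse", "mean")] < agg.loc["gpr-avg", ("mse", "mean")]
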