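"""Benchmark harness: metrics, repeated stratified splits, significance tests.

The comparison protocol fits each method on repeated randomized 70/30
train/test splits (stratified by the simulation clusters when available),
scores predicted ground truth against the true targets, and reports
mean +/- sd per method together with a Friedman omnibus test and pairwise
Wilcoxon signed-rank tests (Bonferroni corrected) on the per-split R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ChainedCrowdGP, TrainingConfig
from .baselines import gpr_avg_fit, gpr_gt_fit
from .simulate import SimulatedTask


@dataclass
class MetricsResult:
    """Standard regression error measures on a test split."""

    mse: float
    mae: float
    mape: float
    r2: float
    epsilon_guard: float = 1e-6

    def as_dict(self):
        return {"mse": self.mse, "mae": self.mae, "mape": self.mape, "r2": self.r2}


def regression_metrics(y_true, y_pred, epsilon_guard: float = 1e-6) -> MetricsResult:
    """MSE, MAE, MAPE (percent, denominator guarded by epsilon) and R^2.

    R^2 is NaN (flagged undefined) when the true targets are constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must share a length of at least 2")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    mape = float(100.0 * np.mean(np.abs(err / (y_true + epsilon_guard))))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = float("nan") if ss_tot <= 0 else 1.0 - float(np.sum(err**2)) / ss_tot
    return MetricsResult(mse, mae, mape, r2, epsilon_guard)


@dataclass
class BenchmarkReport:
    """Per-split metrics, aggregates and the significance table."""

    metrics: pd.DataFrame  # columns: method, split, mse, mae, mape, r2
    splits: list
    seed: int

    def aggregate(self) -> pd.DataFrame:
        return self.metrics.groupby("method")[["mse", "mae", "mape", "r2"]].agg(["mean", "std"])

    def score_table(self, metric: str = "r2") -> pd.DataFrame:
        return self.metrics.pivot(index="split", columns="method", values=metric)


def stratified_split(clusters, train_frac: float, rng: np.random.Generator):
    """Per-cluster random split preserving cluster proportions; clusters with
    fewer than 2 members fall back to the uniform pool with a warning."""
    clusters = np.asarray(clusters)
    n = clusters.size
    train_idx, test_idx, pooled = [], [], []
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if idx.size < 2:
            warnings.warn(f"stratum {c} smaller than 2; assigning uniformly")
            pooled.extend(idx.tolist())
            continue
        idx = rng.permutation(idx)
        k = int(round(train_frac * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.extend(idx[:k].tolist())
        test_idx.extend(idx[k:].tolist())
    if pooled:
        pooled = rng.permutation(np.array(pooled))
        k = int(round(train_frac * len(pooled)))
        train_idx.extend(pooled[:k].tolist())
        test_idx.extend(pooled[k:].tolist())
    return np.sort(np.array(train_idx, int)), np.sort(np.array(test_idx, int))


def uniform_split(n, train_frac, rng):
    idx = rng.permutation(n)
    k = int(round(train_frac * n))
    k = min(max(k, 1), n - 1)
    return np.sort(idx[:k]), np.sort(idx[k:])


def _fit_and_predict(method: str, task: SimulatedTask, train, test,
                     cfg: TrainingConfig, n_factors=None):
    ds = task.dataset().subset(train)
    Xte = task.features[test]
    if method == "crowd-ccgp":
        res = ChainedCrowdGP(ds, n_factors=n_factors).fit(cfg)
        return res.predict_ground_truth(Xte)[0]
    if method == "gpr-avg":
        return gpr_avg_fit(ds, cfg).predict(Xte)[0]
    if method == "gpr-gt":
        sub = SimulatedTask(task.features[train], task.ground_truth[train],
                            task.clusters[train], task.labels[train],
                            task.mask[train], task.profile, task.true_variances,
                            task.seed)
        return gpr_gt_fit(sub, cfg).predict(Xte)[0]
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(task: SimulatedTask, methods: list[str], repeats: int = 15,
                  train_frac: float = 0.7, stratify: bool = True,
                  cfg: TrainingConfig | None = None, seed: int = 0) -> BenchmarkReport:
    """Repeated split evaluation of each method's predicted ground truth.

    All randomness (splits and per-fit seeds) flows from ``seed``.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    base_cfg = cfg or TrainingConfig()
    rng = np.random.default_rng(seed)
    rows, splits = [], []
    for rep in range(repeats):
        if stratify:
            train, test = stratified_split(task.clusters, train_frac, rng)
        else:
            train, test = uniform_split(task.features.shape[0], train_frac, rng)
        splits.append((train, test))
        fit_seed = int(rng.integers(2**31 - 1))
        for method in methods:
            mcfg = TrainingConfig(**{**base_cfg.__dict__, "seed": fit_seed})
            pred = _fit_and_predict(method, task, train, test, mcfg)
            m = regression_metrics(task.ground_truth[test], pred)
            rows.append({"method": method, "split": rep, **m.as_dict()})
    return BenchmarkReport(pd.DataFrame(rows), splits, seed)


def compare_models_significance(scores: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Friedman omnibus plus reference-vs-others Wilcoxon tests on R^2 scores.

    ``scores``: splits x methods table.  Bonferroni correction multiplies each
    raw Wilcoxon p by the number of comparisons (capped at 1).  Identical score
    vectors are flagged degenerate rather than tested.
    """
    methods = list(scores.columns)
    if len(methods) < 2 or scores.shape[0] < 5:
        raise ValueError("need at least 2 methods and 5 splits")
    if reference not in methods:
        raise ValueError(f"reference {reference!r} not among methods")
    cols = [scores[m].to_numpy() for m in methods]
    fr_stat, fr_p = _friedman_omnibus(cols)
    n_comp = len(methods) - 1
    rows = [{"comparison": "friedman", "statistic": float(fr_stat),
             "p_raw": float(fr_p), "p_corrected": float(fr_p), "degenerate": False}]
    ref = scores[reference].to_numpy()
    for m in methods:
        if m == reference:
            continue
        other = scores[m].to_numpy()
        diff = ref - other
        if np.all(diff == 0):
            rows.append({"comparison": f"{reference} vs {m}", "statistic": float("nan"),
                         "p_raw": float("nan"), "p_corrected": float("nan"),
                         "degenerate": True})
            continue
        # exact null for small samples without ties/zeros, else normal approx
        n_eff = int(np.sum(diff != 0))
        method = "exact" if (n_eff <= 25 and not _has_tied_magnitudes(diff)) else "approx"
        stat, p = stats.wilcoxon(ref, other, method=method)
        rows.append({"comparison": f"{reference} vs {m}", "statistic": float(stat),
                     "p_raw": float(p), "p_corrected": min(1.0, float(p) * n_comp),
                     "degenerate": False})
    return pd.DataFrame(rows)


def _friedman_omnibus(cols):
    """Friedman omnibus over paired score columns.

    With exactly two groups the Friedman statistic degenerates and SciPy
    refuses it, so the equivalent exact two-sided sign test on the paired
    differences is used instead (statistic = number of positive differences).
    Identical columns short-circuit to (0, 1).
    """
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        return 0.0, 1.0
    if len(cols) == 2:
        diff = cols[0] - cols[1]
        n_eff = int(np.sum(diff != 0))
        if n_eff == 0:
            return 0.0, 1.0
        k = int(np.sum(diff > 0))
        p = stats.binomtest(k, n_eff, 0.5).pvalue
        return float(k), float(p)
    return stats.friedmanchisquare(*cols)


def _has_tied_magnitudes(diff):
    d = np.abs(diff[diff != 0])
    return np.unique(d).size < d.size or np.any(diff == 0)


def annotator_rank_analysis(trust_means: pd.DataFrame):
    """Rank annotators per attribute by mean trust (rank 1 = most trusted).

    ``trust_means``: annotators x attributes table of mean trust scores.
    Attributes with missing cells are dropped with a warning.  Returns the
    per-attribute rank table, mean rank per annotator, and the Friedman
    statistic/p over the attribute-wise scores.
    """
    df = trust_means.copy()
    bad = [c for c in df.columns if df[c].isna().any()]
    if bad:
        warnings.warn(f"dropping attribute(s) with missing cells: {bad}")
        df = df.drop(columns=bad)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 annotators and 2 attributes")
    # higher trust -> better -> lower rank; ties get average ranks
    ranks = df.rank(axis=0, ascending=False, method="average")
    mean_ranks = ranks.mean(axis=1)
    cols = [df.loc[a].to_numpy() for a in df.index]
    fr_stat, fr_p = _friedman_omnibus(cols)
    return ranks, mean_ranks, float(fr_stat), float(fr_p)
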