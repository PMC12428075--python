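"""Localized annotator trustworthiness and its cluster-level diagnostics.

The trust score compares an annotation's squared residual from the inferred
ground truth against a sublinearly scaled version of the model's posterior
estimate of that annotator's local noise variance:

    T_r(x) = exp( -(y - yhat)^2 / (2 (2 v)^gamma) ),   gamma in (0, 1].

At gamma = 1 the exponent is a scaled Gaussian log-likelihood; smaller gamma
reduces the sensitivity to the predicted uncertainty v and keeps the score
stable where v is small.  Because the variance enters sublinearly, a locally
noisy annotator is only partially forgiven: under a well-calibrated noise
model the expected trust still decreases with the annotator's local noise
level (roughly as exp(-c * v^{1-gamma})), so averaged trust ranks annotators
by local competence.  Scores live in (0, 1] and equal 1 at zero residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr


@dataclass
class TrustConfig:
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")


def trust_score(y, gt_mean, noise_mean, gamma: float = 0.5):
    """Per-annotation trust in (0, 1]; ``noise_mean`` is E[v_r(x)] > 0."""
    y, gt_mean, noise_mean = map(np.asarray, (y, gt_mean, noise_mean))
    if np.any(noise_mean <= 0):
        raise ValueError("noise_mean must be strictly positive")
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    return np.exp(-((y - gt_mean) ** 2) / (2.0 * (2.0 * noise_mean) ** gamma))


@dataclass
class ClusterTrustReport:
    """Annotator x cluster trust and empirical-R^2 matrices (NaN = undefined)."""

    cluster_labels: np.ndarray
    trust_matrix: np.ndarray  # (R, C)
    empirical_r2_matrix: np.ndarray  # (R, C)
    counts: np.ndarray  # samples per cluster


def cluster_trust_matrix(trust_values: np.ndarray, clusters: np.ndarray,
                         mask: np.ndarray) -> np.ndarray:
    """Mean trust per (annotator, cluster) over observed pairs; NaN if empty."""
    trust_values = np.asarray(trust_values, dtype=float)
    clusters = np.asarray(clusters)
    mask = np.asarray(mask, dtype=bool)
    labels = np.unique(clusters)
    R = trust_values.shape[1]
    out = np.full((R, labels.size), np.nan)
    for ci, c in enumerate(labels):
        rows = clusters == c
        for r in range(R):
            sel = rows & mask[:, r]
            if sel.any():
                out[r, ci] = float(np.mean(trust_values[sel, r]))
    return out


def cluster_empirical_r2(Y: np.ndarray, mask: np.ndarray, y_ref: np.ndarray,
                         clusters: np.ndarray) -> np.ndarray:
    """Within-cluster coefficient of determination per annotator.

    For each cluster, 1 - sum (y_nr - y_ref_n)^2 / sum (y_nr - ybar)^2 over
    observed pairs, where ybar is the cluster mean of ``y_ref``.  ``y_ref`` is
    the true target when available (semi-synthetic studies) or the model's
    predicted ground truth otherwise.  Degenerate denominators give NaN; the
    statistic can be negative for annotators worse than the cluster mean.
    """
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    y_ref = np.asarray(y_ref, dtype=float)
    clusters = np.asarray(clusters)
    labels = np.unique(clusters)
    R = Y.shape[1]
    out = np.full((R, labels.size), np.nan)
    for ci, c in enumerate(labels):
        rows = clusters == c
        ybar = float(np.mean(y_ref[rows]))
        for r in range(R):
            sel = rows & mask[:, r]
            if not sel.any():
                continue
            denom = float(np.sum((Y[sel, r] - ybar) ** 2))
            if denom <= 0.0:
                continue  # flagged undefined
            num = float(np.sum((Y[sel, r] - y_ref[sel]) ** 2))
            out[r, ci] = 1.0 - num / denom
    return out


def cluster_trust_report(trust_values, Y, mask, y_ref, clusters) -> ClusterTrustReport:
    clusters = np.asarray(clusters)
    labels, counts = np.unique(clusters, return_counts=True)
    return ClusterTrustReport(
        cluster_labels=labels,
        trust_matrix=cluster_trust_matrix(trust_values, clusters, mask),
        empirical_r2_matrix=cluster_empirical_r2(Y, mask, y_ref, clusters),
        counts=counts,
    )


def trust_r2_agreement(report: ClusterTrustReport) -> float:
    """Pearson correlation between the flattened trust and empirical-R^2 cells."""
    t = report.trust_matrix.ravel()
    e = report.empirical_r2_matrix.ravel()
    ok = np.isfinite(t) & np.isfinite(e)
    if ok.sum() < 3:
        return float("nan")
    return float(pearsonr(t[ok], e[ok]).statistic)


def feature_trust_correlations(features: np.ndarray, trust: np.ndarray,
                               mask: np.ndarray) -> np.ndarray:
    """P x R Pearson correlations between feature values and per-sample trust.

    Computed over the samples each annotator actually rated.  Cells with fewer
    than 3 observations or a constant series are NaN (undefined), never zero.
    """
    features = np.asarray(features, dtype=float)
    trust = np.asarray(trust, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    P, R = features.shape[1], trust.shape[1]
    out = np.full((P, R), np.nan)
    for r in range(R):
        sel = mask[:, r] & np.isfinite(trust[:, r])
        if sel.sum() < 3:
            continue
        tv = trust[sel, r]
        if np.std(tv) == 0.0:
            continue
        for p in range(P):
            fv = features[sel, p]
            if np.std(fv) == 0.0:
                continue
            out[p, r] = float(pearsonr(fv, tv).statistic)
    return out


def trust_report_frame(report: ClusterTrustReport, annotator_ids: list[str]):
    """Tidy (annotator, cluster, statistic, value) table for export."""
    import pandas as pd

    rows = []
    for r, aid in enumerate(annotator_ids):
        for ci, c in enumerate(report.cluster_labels):
            rows.append((aid, int(c), "mean_trust", report.trust_matrix[r, ci]))
            rows.append((aid, int(c), "empirical_r2", report.empirical_r2_matrix[r, ci]))
    return pd.DataFrame(rows, columns=["annotator", "cluster", "statistic", "value"])
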