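"""Multi-annotator regression tables: container, I/O, curation and scaling.

A crowd-sourced regression task pairs an ``N x P`` feature matrix with an
``N x R`` label matrix in which each column holds one annotator's scores and
missing annotations are the norm, not the exception.  Missingness is carried
as an explicit boolean mask; downstream likelihood sums iterate over observed
(sample, annotator) pairs only and never see sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A declared column is absent or a cell cannot be parsed."""


class DegenerateInputError(ValueError):
    """Input data cannot support the requested computation."""


@dataclass
class MultiAnnotatorDataset:
    """Features plus a masked multi-annotator label matrix.

    Attributes
    ----------
    features : ndarray, shape (N, P)
        Numeric inputs; may contain NaN before imputation.
    labels : ndarray, shape (N, R)
        Annotator scores; entries are finite exactly where ``observed_mask``
        is true and NaN elsewhere.
    observed_mask : ndarray of bool, shape (N, R)
        True where annotator r scored sample n.
    """

    features: np.ndarray
    labels: np.ndarray
    observed_mask: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    annotator_ids: list[str] = field(default_factory=list)
    attribute_name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        n, p = self.features.shape
        if n < 1 or p < 1:
            raise ValueError("features must be a non-empty N x P matrix")
        if self.labels.shape != self.observed_mask.shape or self.labels.shape[0] != n:
            raise ValueError("labels/mask shape mismatch with features")
        if self.labels.shape[1] < 1:
            raise ValueError("need at least one annotator column")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(p)]
        if not self.annotator_ids:
            self.annotator_ids = [f"a{i}" for i in range(self.labels.shape[1])]
        if len(set(self.annotator_ids)) != len(self.annotator_ids):
            raise ValueError("annotator_ids must be unique")
        # enforce the labels<->mask invariant
        finite = np.isfinite(self.labels)
        if np.any(finite != self.observed_mask):
            bad = finite & ~self.observed_mask
            lab = self.labels.copy()
            lab[~self.observed_mask] = np.nan
            if np.any(~finite & self.observed_mask):
                raise ValueError("observed_mask true at a non-finite label")
            self.labels = lab if np.any(bad) else self.labels

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_annotators(self) -> int:
        return self.labels.shape[1]

    @property
    def n_observed(self) -> int:
        """Size of the observed index set (the set of rated (n, r) pairs)."""
        return int(self.observed_mask.sum())

    def subset(self, rows: np.ndarray) -> "MultiAnnotatorDataset":
        rows = np.asarray(rows)
        return replace(
            self,
            features=self.features[rows],
            labels=self.labels[rows],
            observed_mask=self.observed_mask[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        for j, a in enumerate(self.annotator_ids):
            col = self.labels[:, j].astype(object)
            col[~self.observed_mask[:, j]] = np.nan
            df[a] = self.labels[:, j]
        return df


def read_annotation_table(
    path,
    feature_columns: list[str],
    annotator_columns: list[str],
    attribute_name: str = "",
) -> MultiAnnotatorDataset:
    """Read a delimited text table into a :class:`MultiAnnotatorDataset`.

    Empty cells in annotator columns become unobserved entries; empty feature
    cells are recorded as NaN for later imputation.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in list(feature_columns) + list(annotator_columns) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing declared column(s): {missing}")

    def parse_block(cols):
        out = np.empty((len(df), len(cols)))
        for j, c in enumerate(cols):
            for i, tok in enumerate(df[c].tolist()):
                if tok is None or (isinstance(tok, float) and np.isnan(tok)) or str(tok).strip() == "":
                    out[i, j] = np.nan
                    continue
                try:
                    out[i, j] = float(tok)
                except ValueError as exc:
                    raise SchemaError(f"non-numeric token {tok!r} at row {i}, column {c!r}") from exc
        return out

    X = parse_block(feature_columns)
    Y = parse_block(annotator_columns)
    mask = np.isfinite(Y)
    return MultiAnnotatorDataset(
        features=X,
        labels=Y,
        observed_mask=mask,
        feature_names=list(feature_columns),
        annotator_ids=list(annotator_columns),
        attribute_name=attribute_name,
    )


def write_dataset(ds: MultiAnnotatorDataset, path) -> None:
    """Write a dataset as CSV so that :func:`read_annotation_table` round-trips."""
    df = pd.DataFrame(ds.features, columns=ds.feature_names)
    for j, a in enumerate(ds.annotator_ids):
        col = ds.labels[:, j].copy()
        col[~ds.observed_mask[:, j]] = np.nan
        df[a] = col
    df.to_csv(path, index=False, float_format="%.17g")


def completeness_filter(
    ds: MultiAnnotatorDataset,
    max_missing_features: int = 1,
    max_missing_labels: int = 1,
) -> MultiAnnotatorDataset:
    """Retain rows with at most the given counts of missing features/labels.

    Mirrors the two curation conditions used to build per-attribute tasks:
    no more than ``max_missing_features`` missing feature cells and no more
    than ``max_missing_labels`` unobserved annotations per sample.
    """
    if max_missing_features < 0 or max_missing_labels < 0:
        raise ValueError("thresholds must be non-negative")
    miss_x = np.sum(~np.isfinite(ds.features), axis=1)
    miss_y = np.sum(~ds.observed_mask, axis=1)
    keep = (miss_x <= max_missing_features) & (miss_y <= max_missing_labels)
    return ds.subset(np.flatnonzero(keep))


def iterative_impute(features: np.ndarray, max_rounds: int = 20, tol: float = 1e-6) -> np.ndarray:
    """Fill missing feature cells by round-robin linear conditional regression.

    Each column with missing entries is regressed (ordinary least squares with
    a tiny diagonal stabilizer) on all other columns over the rows where it is
    observed, and its missing cells are replaced by the fitted values.  Columns
    are visited in a fixed left-to-right order, starting from column-mean
    initialization, until the largest change falls below ``tol`` or
    ``max_rounds`` passes complete.  Observed cells are never modified.
    """
    X = np.array(features, dtype=float)
    n, p = X.shape
    miss = ~np.isfinite(X)
    if not miss.any():
        return X
    for j in range(p):
        if np.sum(~miss[:, j]) < 2:
            raise DegenerateInputError(f"column {j} has fewer than 2 observed values")
    filled = X.copy()
    col_means = np.nanmean(X, axis=0)
    for j in range(p):
        filled[miss[:, j], j] = col_means[j]
    for _ in range(max_rounds):
        max_change = 0.0
        for j in range(p):
            rows = miss[:, j]
            if not rows.any():
                continue
            obs = ~rows
            others = [k for k in range(p) if k != j]
            A = np.column_stack([np.ones(obs.sum()), filled[obs][:, others]])
            b = filled[obs, j]
            # OLS with a tiny ridge purely for numerical stability
            G = A.T @ A + 1e-8 * np.eye(A.shape[1])
            coef = np.linalg.solve(G, A.T @ b)
            Aq = np.column_stack([np.ones(rows.sum()), filled[rows][:, others]])
            new = Aq @ coef
            max_change = max(max_change, float(np.max(np.abs(new - filled[rows, j]), initial=0.0)))
            filled[rows, j] = new
        if max_change < tol:
            break
    return filled


@dataclass
class Standardizer:
    """Per-feature and pooled-target z-scoring with exact inverses."""

    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: float
    target_std: float

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_std

    def inverse_features(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.feature_std + self.feature_mean

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean) / self.target_std

    def inverse_target(self, ys: np.ndarray) -> np.ndarray:
        return ys * self.target_std + self.target_mean

    def inverse_target_variance(self, vs: np.ndarray) -> np.ndarray:
        return vs * self.target_std**2


def fit_apply_standardizer(
    ds: MultiAnnotatorDataset, train_rows: np.ndarray | None = None
) -> tuple[Standardizer, MultiAnnotatorDataset]:
    """Z-score features per column and labels on one pooled target scale.

    Statistics come from ``train_rows`` only (default: all rows).  A single
    target mean/sd pooled over all observed training labels is used because
    the likelihood shares one latent ground truth across annotators.
    """
    if train_rows is None:
        train_rows = np.arange(ds.n_samples)
    train_rows = np.asarray(train_rows)
    if train_rows.size == 0:
        raise ValueError("train_rows must be non-empty")
    Xt = ds.features[train_rows]
    mu = np.nanmean(Xt, axis=0)
    sd = np.nanstd(Xt, axis=0, ddof=0)
    if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
        bad = [ds.feature_names[i] for i in np.flatnonzero(~(sd > 0))]
        raise DegenerateInputError(f"constant feature column(s): {bad}")
    yt = ds.labels[train_rows][ds.observed_mask[train_rows]]
    if yt.size == 0:
        raise DegenerateInputError("no observed training labels")
    ty, tsd = float(np.mean(yt)), float(np.std(yt, ddof=0))
    if tsd <= 0:
        raise DegenerateInputError("observed training labels are constant")
    std = Standardizer(mu, sd, ty, tsd)
    labels = np.where(ds.observed_mask, (ds.labels - ty) / tsd, np.nan)
    out = replace(ds, features=std.transform_features(ds.features), labels=labels)
    return std, out
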