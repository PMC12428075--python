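"""Single-output sparse GP baselines: consensus-average and oracle regressors.

Both baselines reuse the chained engine with a single latent function and a
learned constant Gaussian noise variance.  ``gpr_avg_fit`` trains on the
per-sample mean of observed annotations (naive consensus, uniform-reliability
assumption); ``gpr_gt_fit`` trains on the true targets and serves as the
oracle upper bound on simulated tasks.  After Adam optimization of the
hyperparameters, the variational posterior receives one exact coordinate-
ascent update, which is optimal for the conjugate Gaussian likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MultiAnnotatorDataset
from .kernels import RBFKernel, rbf_gram
from .lmc import jittered_cholesky, lf_predictive_marginals
from .model import (
    ChainedLikelihoodConfig,
    TrainingConfig,
    conjugate_variational_update,
    fit_variational,
)


@dataclass
class SparseGPRegressor:
    """Fitted single-output sparse variational GP with constant noise."""

    params: object
    noise_variance: float
    y_mean: float
    y_std: float
    x_mean: np.ndarray
    x_std: np.ndarray
    elbo_trace: list

    def predict(self, Xq: np.ndarray, include_noise: bool = False):
        Xs = (np.atleast_2d(np.asarray(Xq, dtype=float)) - self.x_mean) / self.x_std
        model, state = self.params.to_model_state()
        marg = lf_predictive_marginals(model, state, Xs)
        mean = marg.means[0] * self.y_std + self.y_mean
        var = marg.variances[0] * self.y_std**2
        if include_noise:
            var = var + self.noise_variance * self.y_std**2
        return mean, var


def fit_sparse_gp(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig,
                  n_rounds: int = 4) -> SparseGPRegressor:
    """Fit a homoscedastic sparse GP regressor on (X, y) with standardization.

    Training alternates gradient steps on all parameters with the exact
    coordinate-ascent update of the variational posterior, which is available
    in closed form for the conjugate Gaussian likelihood.  The warm-started
    posterior keeps the noise variance from absorbing unexplained signal
    early in optimization; ``cfg.max_steps`` is split across the rounds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    xm, xs = X.mean(axis=0), X.std(axis=0)
    xs = np.where(xs > 0, xs, 1.0)
    ym, ysd = float(y.mean()), float(y.std())
    ysd = ysd if ysd > 0 else 1.0
    Xs, ys = (X - xm) / xs, (y - ym) / ysd
    lik = ChainedLikelihoodConfig(1, "constant")
    mask = np.ones((y.size, 1), bool)
    n_rounds = max(1, int(n_rounds))
    round_cfg = TrainingConfig(**{**cfg.__dict__,
                                  "max_steps": max(1, cfg.max_steps // n_rounds)})
    params, trace = None, []
    for _ in range(n_rounds):
        if params is not None:
            params = conjugate_variational_update(
                params, Xs, ys, float(np.exp(params.log_noise[0])))
        params, tr = fit_variational(Xs, ys[:, None], mask, round_cfg, lik,
                                     n_factors=1, init=params)
        trace.extend(tr)
    sigma2 = float(np.exp(params.log_noise[0]))
    params = conjugate_variational_update(params, Xs, ys, sigma2)
    return SparseGPRegressor(params, sigma2, ym, ysd, xm, xs, trace)


def gpr_avg_fit(ds: MultiAnnotatorDataset, cfg: TrainingConfig) -> SparseGPRegressor:
    """GP regression on the per-sample average of observed annotations."""
    counts = ds.observed_mask.sum(axis=1)
    keep = counts > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {int((~keep).sum())} sample(s) with no observed labels")
    ybar = np.nansum(np.where(ds.observed_mask, ds.labels, 0.0), axis=1)[keep] / counts[keep]
    return fit_sparse_gp(ds.features[keep], ybar, cfg)


def gpr_gt_fit(task, cfg: TrainingConfig) -> SparseGPRegressor:
    """Oracle GP regression on the true targets of a simulated task."""
    gt = getattr(task, "ground_truth", None)
    if gt is None:
        raise ValueError("ground truth unavailable: oracle baseline needs a simulated task")
    return fit_sparse_gp(task.features, gt, cfg)


def exact_gp_posterior(kernel: RBFKernel, X: np.ndarray, y: np.ndarray,
                       sigma2: float, Xq: np.ndarray):
    """Textbook exact GP regression posterior mean/variance and log marginal
    likelihood, used as the closed-form reference in conjugate-regime checks."""
    X = np.atleast_2d(X)
    Xq = np.atleast_2d(Xq)
    N = X.shape[0]
    K = rbf_gram(kernel, X, X) + sigma2 * np.eye(N)
    L, _ = jittered_cholesky(K, jitter=0.0)
    from scipy.linalg import cho_solve

    alpha = cho_solve((L, True), y)
    Ks = rbf_gram(kernel, Xq, X)
    mean = Ks @ alpha
    var = kernel.variance - np.sum(Ks * cho_solve((L, True), Ks.T).T, axis=1)
    lml = float(-0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * N * np.log(2 * np.pi))
    return mean, np.maximum(var, 0.0), lml
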