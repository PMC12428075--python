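"""Shared-latent-factor (coregionalized) GP machinery.

``J`` latent functions are built as weighted sums of ``Q`` independent factor
GPs, ``f_j(x) = sum_q w[j,q] * g_q(x)``, so the covariance between any two
latent functions is induced by the shared factors.  Each factor carries its
own set of ``M`` inducing inputs and a Gaussian variational posterior over the
inducing values, stored via a lower-triangular square root so that positive
definiteness survives gradient updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.cluster import KMeans

from .kernels import RBFKernel, rbf_gram

JITTER = 1e-6
JITTER_MAX = 1e-2


def jittered_cholesky(K: np.ndarray, jitter: float = JITTER):
    """Lower Cholesky of ``K + jitter*I``, escalating jitter x10 up to 1e-2."""
    j = jitter
    while j <= JITTER_MAX:
        try:
            L = cholesky(K + j * np.eye(K.shape[0]), lower=True)
            return L, j
        except np.linalg.LinAlgError:
            j = JITTER if j == 0.0 else j * 10.0
    raise np.linalg.LinAlgError("matrix not positive definite even at maximum jitter")


@dataclass
class LatentFactorModel:
    """Q factor GPs with RBF kernels, per-factor inducing sets, J x Q mixing weights."""

    kernels: list[RBFKernel]
    inducing_inputs: list[np.ndarray]  # Q arrays of shape (M, P)
    mixing_weights: np.ndarray  # (J, Q)

    def __post_init__(self) -> None:
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        if len(self.kernels) != len(self.inducing_inputs):
            raise ValueError("one inducing set per factor required")
        if self.mixing_weights.shape[1] != len(self.kernels):
            raise ValueError("mixing weight columns must match factor count")
        m0 = self.inducing_inputs[0].shape[0]
        if any(Z.shape[0] != m0 for Z in self.inducing_inputs):
            raise ValueError("all inducing sets must share M")
        if not np.all(np.isfinite(self.mixing_weights)):
            raise ValueError("mixing weights must be finite")

    @property
    def n_factors(self) -> int:
        return len(self.kernels)

    @property
    def n_latent(self) -> int:
        return self.mixing_weights.shape[0]

    @property
    def n_inducing(self) -> int:
        return self.inducing_inputs[0].shape[0]


@dataclass
class VariationalState:
    """Per-factor Gaussian posteriors over inducing values, V_q = L_q L_q^T."""

    means: list[np.ndarray]  # Q vectors of length M
    cov_sqrts: list[np.ndarray]  # Q lower-triangular (M, M)

    @classmethod
    def at_prior(cls, model: LatentFactorModel) -> "VariationalState":
        """Initialize q(u_q) = N(0, K_q): zero KL, marginals equal the prior."""
        means, sqrts = [], []
        for kern, Z in zip(model.kernels, model.inducing_inputs):
            K = rbf_gram(kern, Z, Z)
            L, _ = jittered_cholesky(K)
            means.append(np.zeros(Z.shape[0]))
            sqrts.append(L)
        return cls(means, sqrts)

    def covariances(self) -> list[np.ndarray]:
        return [L @ L.T for L in self.cov_sqrts]


def lmc_marginal_cov(model: LatentFactorModel, j: int, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Covariance of latent function j: sum_q w[j,q]^2 * k_q(A, B)."""
    w = model.mixing_weights[j]
    out = np.zeros((np.atleast_2d(A).shape[0], np.atleast_2d(B).shape[0]))
    for q, kern in enumerate(model.kernels):
        if w[q] != 0.0:
            out += w[q] ** 2 * rbf_gram(kern, A, B)
    return out


def lmc_cross_cov(model: LatentFactorModel, j: int, A: np.ndarray, q: int) -> np.ndarray:
    """Cross-covariance of latent function j with factor q's inducing values."""
    return model.mixing_weights[j, q] * rbf_gram(model.kernels[q], A, model.inducing_inputs[q])


def gaussian_kl(q_mean: np.ndarray, q_cov: np.ndarray, p_cov: np.ndarray) -> float:
    """KL( N(q_mean, q_cov) || N(0, p_cov) ) via the closed Gaussian form."""
    m = q_mean.size
    Lp, _ = jittered_cholesky(p_cov, jitter=0.0)
    Lq, _ = jittered_cholesky(q_cov, jitter=0.0)
    alpha = solve_triangular(Lp, q_mean, lower=True)
    W = solve_triangular(Lp, Lq, lower=True)
    trace = float(np.sum(W**2))
    logdet_p = 2.0 * float(np.sum(np.log(np.diag(Lp))))
    logdet_q = 2.0 * float(np.sum(np.log(np.diag(Lq))))
    return 0.5 * (trace + float(alpha @ alpha) - m + logdet_p - logdet_q)


@dataclass
class LFMarginal:
    """Marginal mean and variance of each latent function at query points."""

    means: np.ndarray  # (J, n)
    variances: np.ndarray  # (J, n), clipped at 0


def factor_predictive_terms(
    model: LatentFactorModel, state: VariationalState, Xq: np.ndarray
):
    """Per-factor predictive mean/variance pieces at Xq.

    Returns arrays ``m`` and ``s`` of shape (Q, n): for factor q,
    ``m[q] = k_xz K^-1 mu_q`` and
    ``s[q] = k(x,x) - k_xz K^-1 k_zx + a^T V_q a`` with ``a = K^-1 k_zx``.
    These combine into latent-function marginals as
    mean_j = sum_q w[j,q] m[q], var_j = sum_q w[j,q]^2 s[q].
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    n = Xq.shape[0]
    Q = model.n_factors
    m = np.empty((Q, n))
    s = np.empty((Q, n))
    for q in range(Q):
        kern, Z = model.kernels[q], model.inducing_inputs[q]
        K = rbf_gram(kern, Z, Z)
        Lk, _ = jittered_cholesky(K)
        B = rbf_gram(kern, Xq, Z)
        A = cho_solve((Lk, True), B.T).T  # n x M, rows a_n^T
        m[q] = A @ state.means[q]
        T = A @ state.cov_sqrts[q]
        s[q] = kern.variance - np.sum(B * A, axis=1) + np.sum(T**2, axis=1)
    return m, s


def lf_predictive_marginals(
    model: LatentFactorModel, state: VariationalState, Xq: np.ndarray
) -> LFMarginal:
    """Variational marginals of every latent function at the query points."""
    m, s = factor_predictive_terms(model, state, Xq)
    W = model.mixing_weights
    means = W @ m
    variances = (W**2) @ s
    return LFMarginal(means=means, variances=np.maximum(variances, 0.0))


def init_inducing_kmeans(X: np.ndarray, M: int, seed: int) -> np.ndarray:
    """K-means centers of X as initial inducing inputs (deterministic per seed)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if M > X.shape[0]:
        raise ValueError("cannot place more inducing points than data points")
    km = KMeans(n_clusters=M, n_init=1, max_iter=100, random_state=seed)
    km.fit(X)
    return km.cluster_centers_.astype(float)
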