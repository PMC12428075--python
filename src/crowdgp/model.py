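"""Crowd regression with a correlated chained sparse variational GP.

The observation model for annotator r on sample n is

    y_nr ~ N( f_1(x_n), exp(f_{1+r}(x_n)) ),

so one latent function carries the shared ground truth (identity link) and
one latent function per annotator carries that annotator's log noise variance
(exponential link, keeping the variance strictly positive).  All J = R + 1
latent functions are linear combinations of Q shared factor GPs, each factor
approximated with M inducing variables and a Gaussian variational posterior.
Training maximizes the evidence lower bound (expected log likelihood over
observed (n, r) pairs minus per-factor KL terms) by Adam over the variational
parameters, mixing weights, ARD log-lengthscales and inducing inputs, with
all gradients computed in closed form.

A ``statsmodels``-style surface wraps the machinery: build a
:class:`ChainedCrowdGP` from data, call :meth:`~ChainedCrowdGP.fit`, and work
with the returned :class:`ChainedCrowdGPResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .data import MultiAnnotatorDataset, Standardizer, fit_apply_standardizer
from .kernels import RBFKernel, rbf_gram, rbf_gram_grads
from .likelihood import (
    expected_log_density,
    expected_log_density_grads,
    lognormal_moments,
)
from .lmc import (
    LatentFactorModel,
    VariationalState,
    factor_predictive_terms,
    gaussian_kl,
    init_inducing_kmeans,
    jittered_cholesky,
    lf_predictive_marginals,
    rbf_gram as _gram,
)

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TrainingConfig:
    """Optimization settings for the sparse variational fit."""

    n_inducing: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-2
    max_steps: int = 1000
    plateau_patience: int = 20
    lr_floor: float = 1e-6
    stop_patience: int = 500
    eval_every: int = 10
    improvement_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_inducing, self.batch_size, self.max_steps, self.plateau_patience,
               self.stop_patience, self.eval_every) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 < self.lr_floor < self.learning_rate):
            raise ValueError("need 0 < lr_floor < learning_rate")


@dataclass
class ChainedLikelihoodConfig:
    """Latent-function layout: index 0 = ground truth, 1..R = log-variance LFs.

    ``noise_model="chained"`` gives each annotator an input-dependent GP log
    variance; ``"constant"`` replaces those LFs with one scalar log variance
    per annotator (used by the homoscedastic baselines and conjugate checks).
    """

    n_annotators: int
    noise_model: str = "chained"

    @property
    def n_latent(self) -> int:
        return 1 + self.n_annotators if self.noise_model == "chained" else 1


# ---------------------------------------------------------------------------
# Parameter bundle


@dataclass
class _Params:
    log_ell: np.ndarray  # (Q, P)
    Z: np.ndarray  # (Q, M, P)
    W: np.ndarray  # (J, Q)
    mu: np.ndarray  # (Q, M)
    L: np.ndarray  # (Q, M, M) lower triangular
    log_noise: np.ndarray  # (R,) used only in constant-noise mode

    def copy(self) -> "_Params":
        return _Params(*(np.array(getattr(self, f)) for f in
                         ("log_ell", "Z", "W", "mu", "L", "log_noise")))

    def keys(self):
        return ("log_ell", "Z", "W", "mu", "L", "log_noise")

    def to_model_state(self) -> tuple[LatentFactorModel, VariationalState]:
        Q = self.log_ell.shape[0]
        kernels = [RBFKernel(np.exp(self.log_ell[q])) for q in range(Q)]
        model = LatentFactorModel(kernels, [self.Z[q] for q in range(Q)], self.W)
        state = VariationalState([self.mu[q] for q in range(Q)],
                                 [np.tril(self.L[q]) for q in range(Q)])
        return model, state


def _init_params(X: np.ndarray, cfg: TrainingConfig, lik: ChainedLikelihoodConfig,
                 n_factors: int, rng: np.random.Generator) -> _Params:
    N, P = X.shape
    M = min(cfg.n_inducing, N)
    Q, J = n_factors, lik.n_latent
    Z0 = init_inducing_kmeans(X, M, seed=int(rng.integers(2**31 - 1)))
    log_ell = np.zeros((Q, P))
    Z = np.repeat(Z0[None], Q, axis=0).copy()
    # identity-dominant mixing: each latent function gets a dedicated factor
    # at init (plus small cross-loadings), which keeps the closed-form factor
    # updates well targeted early in training
    W = rng.normal(0.0, 0.1, size=(J, Q))
    for j in range(min(J, Q)):
        W[j, j] = 1.0
    mu = np.zeros((Q, M))
    L = np.empty((Q, M, M))
    for q in range(Q):
        K = rbf_gram(RBFKernel(np.exp(log_ell[q])), Z[q], Z[q])
        Lq, _ = jittered_cholesky(K)
        L[q] = Lq
    log_noise = np.full(lik.n_annotators, np.log(0.1))
    return _Params(log_ell, Z, W, mu, L, log_noise)


# ---------------------------------------------------------------------------
# ELBO and closed-form gradients


def _elbo_and_grads(params: _Params, X: np.ndarray, Y: np.ndarray, mask: np.ndarray,
                    rows: np.ndarray, scale: float, lik: ChainedLikelihoodConfig,
                    want_grads: bool = True):
    """Minibatch ELBO estimate and its gradients.

    ``scale`` is (total observed pairs) / (observed pairs in batch rows) so the
    data term is an unbiased estimate of the full sum; the KL term is exact.
    """
    Q, M, P = params.Z.shape
    J = params.W.shape[0]
    R = lik.n_annotators
    chained = lik.noise_model == "chained"
    Xb = X[rows]
    Yb = np.where(mask[rows], np.nan_to_num(Y[rows]), 0.0)
    Mb = mask[rows]
    n = Xb.shape[0]
    W = params.W

    # per-factor forward pass, caching solves for the backward pass
    cache = []
    m_f = np.empty((Q, n))
    s_f = np.empty((Q, n))
    for q in range(Q):
        kern = RBFKernel(np.exp(params.log_ell[q]))
        Zq = params.Z[q]
        K = rbf_gram(kern, Zq, Zq)
        LK, jit = jittered_cholesky(K)
        B = rbf_gram(kern, Xb, Zq)
        A = cho_solve((LK, True), B.T).T
        beta = cho_solve((LK, True), params.mu[q])
        Lq = np.tril(params.L[q])
        T = A @ Lq
        m_f[q] = B @ beta
        s_f[q] = kern.variance - np.sum(B * A, axis=1) + np.sum(T**2, axis=1)
        cache.append((kern, Zq, K, LK, B, A, beta, Lq))

    mean = W @ m_f  # (J, n)
    var = np.maximum((W**2) @ s_f, 0.0)

    m1, s1 = mean[0], var[0]
    if chained:
        mlr = mean[1:].T  # (n, R)
        slr = var[1:].T
    else:
        mlr = np.broadcast_to(params.log_noise, (n, R))
        slr = np.zeros((n, R))

    E = np.exp(-mlr + 0.5 * slr)
    resid = Yb - m1[:, None]
    quad = resid**2 + s1[:, None]
    ell_terms = -0.5 * LOG2PI - 0.5 * mlr - 0.5 * quad * E
    data_term = scale * float(np.sum(np.where(Mb, ell_terms, 0.0)))

    # KL divergence per factor (exact, never scaled)
    kl_total = 0.0
    kl_parts = []
    for q in range(Q):
        kern, Zq, K, LK, B, A, beta, Lq = cache[q]
        alpha = solve_triangular(LK, params.mu[q], lower=True)
        Wm = solve_triangular(LK, Lq, lower=True)
        logdet_K = 2.0 * np.sum(np.log(np.diag(LK)))
        diagL = np.abs(np.diag(Lq))
        logdet_V = 2.0 * np.sum(np.log(diagL))
        kl = 0.5 * (np.sum(Wm**2) + alpha @ alpha - M + logdet_K - logdet_V)
        kl_total += float(kl)
        kl_parts.append((alpha, Wm))
    elbo_val = data_term - kl_total
    if not want_grads:
        return elbo_val, None

    # --- backward pass ---------------------------------------------------
    g = _Params(np.zeros_like(params.log_ell), np.zeros_like(params.Z),
                np.zeros_like(params.W), np.zeros_like(params.mu),
                np.zeros_like(params.L), np.zeros_like(params.log_noise))

    Em = np.where(Mb, E, 0.0)
    d_m1 = np.sum(resid * Em, axis=1)  # (n,)
    d_s1 = -0.5 * np.sum(Em, axis=1)
    d_ml = np.where(Mb, -0.5 + 0.5 * quad * E, 0.0)  # (n, R)
    d_sl = np.where(Mb, -0.25 * quad * E, 0.0)

    Gmean = np.zeros((J, n))
    Gvar = np.zeros((J, n))
    Gmean[0] = scale * d_m1
    Gvar[0] = scale * d_s1
    if chained:
        Gmean[1:] = scale * d_ml.T
        Gvar[1:] = scale * d_sl.T
    else:
        g.log_noise += scale * np.sum(d_ml, axis=0)

    # chain into per-factor adjoints
    Gm = W.T @ Gmean  # (Q, n)
    Gs = (W**2).T @ Gvar
    g.W += Gmean @ m_f.T + 2.0 * W * (Gvar @ s_f.T)

    eye = np.eye(M)
    for q in range(Q):
        kern, Zq, K, LK, B, A, beta, Lq = cache[q]
        Gm_q, Gs_q = Gm[q], Gs[q]
        Vq = Lq @ Lq.T

        # data-term pieces
        g.mu[q] += A.T @ Gm_q
        AG = A * Gs_q[:, None]
        GV = AG.T @ A  # symmetric adjoint on V_q
        D = A @ Vq
        C = cho_solve((LK, True), D.T).T
        Gbar_B = Gm_q[:, None] * beta[None, :] + 2.0 * Gs_q[:, None] * (C - A)
        Gbar_K = (-np.outer(A.T @ Gm_q, beta)
                  + GV - AG.T @ C - (C * Gs_q[:, None]).T @ A)

        # KL pieces (subtracted from the ELBO)
        Kinv = cho_solve((LK, True), eye)
        g.mu[q] -= cho_solve((LK, True), params.mu[q])
        Vinv = cho_solve((np.linalg.cholesky(Vq + 1e-12 * eye), True), eye)
        GV_kl = 0.5 * (Kinv - Vinv)
        GV_total = GV - GV_kl
        g.L[q] += np.tril(2.0 * GV_total @ Lq)
        bb = np.outer(cho_solve((LK, True), params.mu[q]), cho_solve((LK, True), params.mu[q]))
        Gbar_K -= 0.5 * (Kinv - Kinv @ Vq @ Kinv - bb)

        # kernel hyperparameter / inducing input chain
        gl_K, gZ_K = rbf_gram_grads(kern, Zq, Zq, K, Gbar_K, symmetric=True)
        gl_B, gZ_B = rbf_gram_grads(kern, Xb, Zq, B, Gbar_B, symmetric=False)
        g.log_ell[q] += gl_K + gl_B
        g.Z[q] += gZ_K + gZ_B

    return elbo_val, g


def elbo(ds: MultiAnnotatorDataset, model: LatentFactorModel, state: VariationalState,
         batch: np.ndarray | None = None, noise_model: str = "chained",
         log_noise: np.ndarray | None = None) -> float:
    """Reference ELBO over an explicit set of observed (n, r) pairs.

    ``batch`` is an integer array of shape (k, 2) listing observed pairs; with
    ``batch=None`` all observed pairs enter and the scaling factor is 1.  This
    path goes through :func:`lf_predictive_marginals` and is used to
    cross-check the fused training objective.
    """
    obs = np.argwhere(ds.observed_mask)
    if batch is None:
        batch = obs
    batch = np.asarray(batch)
    kl = 0.0
    for q in range(model.n_factors):
        K = _gram(model.kernels[q], model.inducing_inputs[q], model.inducing_inputs[q])
        V = state.cov_sqrts[q] @ state.cov_sqrts[q].T
        kl += gaussian_kl(state.means[q], V, K)
    if batch.size == 0:
        return -kl
    scale = obs.shape[0] / batch.shape[0]
    rows = batch[:, 0]
    marg = lf_predictive_marginals(model, state, ds.features[rows])
    total = 0.0
    for i, (nrow, r) in enumerate(batch):
        y = ds.labels[nrow, r]
        if noise_model == "chained":
            ml, sl = marg.means[1 + r, i], marg.variances[1 + r, i]
        else:
            ml, sl = float(log_noise[r]), 0.0
        total += float(expected_log_density(y, marg.means[0, i], marg.variances[0, i], ml, sl))
    return scale * total - kl


# ---------------------------------------------------------------------------
# Optimizer


class _Adam:
    def __init__(self, params: _Params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(getattr(params, k)) for k in params.keys()}
        self.v = {k: np.zeros_like(getattr(params, k)) for k in params.keys()}
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params: _Params, grads: _Params, lr: float, trainable: set[str]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in trainable:
            gk = getattr(grads, k)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            # gradient ascent on the ELBO
            setattr(params, k, getattr(params, k) + lr * mhat / (np.sqrt(vhat) + self.eps))


DEFAULT_TRAINABLE = {"log_ell", "Z", "W", "mu", "L", "log_noise"}


def fit_variational(X: np.ndarray, Y: np.ndarray, mask: np.ndarray,
                    cfg: TrainingConfig, lik: ChainedLikelihoodConfig,
                    n_factors: int | None = None,
                    trainable: set[str] | None = None,
                    init: _Params | None = None,
                    warm_start: bool = False,
                    mean_updates: bool = False):
    """Maximize the ELBO by minibatch Adam; deterministic given ``cfg.seed``.

    Minibatches are drawn over sample rows (all of a row's observed labels
    enter together).  The full-data ELBO is evaluated every ``eval_every``
    steps; the learning rate halves after ``plateau_patience`` non-improving
    evaluations (floored at ``lr_floor``) and training stops after
    ``stop_patience`` non-improving evaluations or ``max_steps`` steps.  The
    best-scoring parameters are restored at the end.

    Returns ``(params, trace)`` where ``trace`` is the list of full-data ELBO
    evaluations (the initial value first).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("no observed labels to fit on")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix must be complete (impute first)")
    N = X.shape[0]
    if n_factors is None:
        n_factors = lik.n_latent
    rng = np.random.default_rng(cfg.seed)
    params = init.copy() if init is not None else _init_params(X, cfg, lik, n_factors, rng)
    if warm_start and init is None:
        params = warm_start_ground_truth_factor(params, X, Y, mask)
    trainable = set(trainable) if trainable is not None else set(DEFAULT_TRAINABLE)
    if lik.noise_model == "chained":
        trainable.discard("log_noise")

    n_obs_total = int(mask.sum())
    all_rows = np.arange(N)

    def full_elbo(p):
        val, _ = _elbo_and_grads(p, X, Y, mask, all_rows, 1.0, lik, want_grads=False)
        return val

    opt = _Adam(params)
    lr = cfg.learning_rate
    best_val = full_elbo(params)
    best_params = params.copy()
    trace = [best_val]
    plateau = stale = 0
    batch = min(cfg.batch_size, N)
    for step in range(1, cfg.max_steps + 1):
        rows = rng.choice(N, size=batch, replace=False)
        n_obs_batch = int(mask[rows].sum())
        if n_obs_batch == 0:
            continue
        scale = n_obs_total / n_obs_batch
        val, grads = _elbo_and_grads(params, X, Y, mask, rows, scale, lik)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite ELBO at step {step}")
        opt.step(params, grads, lr, trainable)
        if step % cfg.eval_every == 0 or step == cfg.max_steps:
            cur = full_elbo(params)
            if mean_updates:
                # closed-form factor updates (ground-truth factor exactly,
                # noise factors via the log squared residual surrogate), each
                # kept only if the full bound does not decrease
                for update in (chained_mean_factor_update, noise_factor_update):
                    cand = update(params, X, Y, mask, lik)
                    cand_val = full_elbo(cand)
                    if cand_val >= cur:
                        params = cand
                        cur = cand_val
            trace.append(cur)
            if cur > best_val + cfg.improvement_tol:
                best_val = cur
                best_params = params.copy()
                plateau = stale = 0
            else:
                plateau += 1
                stale += 1
            if plateau >= cfg.plateau_patience:
                lr = max(lr / 2.0, cfg.lr_floor)
                plateau = 0
            if stale >= cfg.stop_patience:
                break
    return best_params, trace


def warm_start_ground_truth_factor(params: _Params, X: np.ndarray, Y: np.ndarray,
                                   mask: np.ndarray, sigma2: float = 0.1) -> _Params:
    """Conjugate warm start of the ground-truth factor's variational posterior.

    Treats the per-sample average of observed labels as a Gaussian observation
    of ``W[0, 0] * g_0`` with variance ``sigma2 / n_labels`` and sets
    ``q(u_0)`` to the exact coordinate-ascent optimum of that surrogate bound.
    Starting from a signal-bearing ground-truth posterior steers optimization
    away from the trivial solution in which the noise latent functions absorb
    the signal while the mean function stays flat.
    """
    counts = mask.sum(axis=1)
    keep = counts > 0
    ybar = np.nansum(np.where(mask, np.nan_to_num(Y), 0.0), axis=1)[keep] / counts[keep]
    prec = counts[keep] / sigma2  # per-sample observation precision
    w = float(params.W[0, 0])
    kern = RBFKernel(np.exp(params.log_ell[0]))
    Z = params.Z[0]
    K = rbf_gram(kern, Z, Z)
    LK, _ = jittered_cholesky(K)
    Kzx = rbf_gram(kern, Z, X[keep])
    Pm = cho_solve((LK, True), Kzx)
    eyeM = np.eye(Z.shape[0])
    Kinv = cho_solve((LK, True), eyeM)
    Lam = Kinv + w**2 * (Pm * prec) @ Pm.T
    Llam = np.linalg.cholesky(Lam)
    V = cho_solve((Llam, True), eyeM)
    mu = w * (V @ (Pm @ (prec * ybar)))
    out = params.copy()
    out.mu[0] = mu
    out.L[0] = np.linalg.cholesky(V + 1e-12 * eyeM)
    return out


def chained_mean_factor_update(params: _Params, X: np.ndarray, Y: np.ndarray,
                               mask: np.ndarray,
                               lik: ChainedLikelihoodConfig) -> _Params:
    """Exact coordinate-ascent update of q(u_0) in the chained model.

    For fixed noise latent functions the expected log density is Gaussian in
    the mean function f_1 with per-pair precision ``rho = exp(-m_l + s_l/2)``
    (``1/sigma_r^2`` for constant noise), so the optimal q(u_0) is available
    in closed form: the conjugate update with per-sample precision summed over
    that sample's observed annotators and targets shifted by the other
    factors' contribution to f_1.  The step never decreases the bound and
    substitutes for the natural-gradient updates the non-conjugate chained
    likelihood otherwise forbids.
    """
    model, state = params.to_model_state()
    m_f, s_f = factor_predictive_terms(model, state, X)
    R = lik.n_annotators
    w_row = params.W[0]  # mixing weights of the ground-truth output
    if lik.noise_model == "chained":
        ml = params.W[1:1 + R] @ m_f  # (R, N)
        sl = (params.W[1:1 + R] ** 2) @ s_f
        rho = np.exp(-ml.T + sl.T / 2.0)  # (N, R)
    else:
        rho = np.broadcast_to(np.exp(-params.log_noise)[None, :], mask.shape)
    rho = np.where(mask, rho, 0.0)
    prec = rho.sum(axis=1)
    keep = prec > 0
    Yz = np.where(mask, np.nan_to_num(Y), 0.0)
    ybar = (rho * Yz).sum(axis=1)[keep] / prec[keep]
    # mean contribution of the other factors to f_1
    other = (w_row[1:, None] * m_f[1:]).sum(axis=0) if m_f.shape[0] > 1 else 0.0
    target = ybar - (other[keep] if np.ndim(other) else 0.0)
    w = float(w_row[0])
    if w == 0.0:
        return params
    kern = RBFKernel(np.exp(params.log_ell[0]))
    Z = params.Z[0]
    K = rbf_gram(kern, Z, Z)
    LK, _ = jittered_cholesky(K)
    Kzx = rbf_gram(kern, Z, X[keep])
    Pm = cho_solve((LK, True), Kzx)
    eyeM = np.eye(Z.shape[0])
    Kinv = cho_solve((LK, True), eyeM)
    Lam = Kinv + w**2 * (Pm * prec[keep]) @ Pm.T
    Llam = np.linalg.cholesky(Lam)
    V = cho_solve((Llam, True), eyeM)
    mu = w * (V @ (Pm @ (prec[keep] * target)))
    out = params.copy()
    out.mu[0] = mu
    out.L[0] = np.linalg.cholesky(V + 1e-12 * eyeM)
    return out


#: log chi^2_1 moments: E[log chi^2_1] = log 2 + psi(1/2), var = pi^2 / 2
_LOG_CHI2_MEAN = -1.2703628454614782
_LOG_CHI2_VAR = np.pi**2 / 2.0


def noise_factor_update(params: _Params, X: np.ndarray, Y: np.ndarray,
                        mask: np.ndarray,
                        lik: ChainedLikelihoodConfig) -> _Params:
    """Moment-matched update of the noise factors' variational posteriors.

    Under the model, ``log((y - f_1)^2)`` equals the log-variance function
    ``f_{1+r}`` plus log chi-square(1) noise, so each annotator's dedicated
    factor receives a conjugate GP-regression update on the bias-corrected
    log squared residuals (surrogate observation variance pi^2/2).  This is
    an approximation, not exact coordinate ascent; callers should keep the
    result only if the bound does not decrease.  Requires the
    identity-dominant factor layout (Q = J) and a chained noise model.
    """
    Q, J = params.Z.shape[0], params.W.shape[0]
    if lik.noise_model != "chained" or Q != J:
        return params
    model, state = params.to_model_state()
    m_f, s_f = factor_predictive_terms(model, state, X)
    m1 = params.W[0] @ m_f
    s1 = (params.W[0] ** 2) @ s_f
    out = params.copy()
    eyeM = np.eye(params.Z.shape[1])
    for r in range(lik.n_annotators):
        j = 1 + r
        w = float(params.W[j, j])
        if w == 0.0:
            continue
        sel = mask[:, r]
        if sel.sum() < 2:
            continue
        resid2 = (Y[sel, r] - m1[sel]) ** 2 + s1[sel]
        t = np.log(np.maximum(resid2, 1e-12)) - _LOG_CHI2_MEAN
        # subtract the other factors' mean contribution to f_j
        other = params.W[j] @ m_f[:, sel] - w * m_f[j, sel]
        target = t - other
        kern = RBFKernel(np.exp(params.log_ell[j]))
        Z = params.Z[j]
        K = rbf_gram(kern, Z, Z)
        LK, _ = jittered_cholesky(K)
        Kzx = rbf_gram(kern, Z, X[sel])
        Pm = cho_solve((LK, True), Kzx)
        Kinv = cho_solve((LK, True), eyeM)
        Lam = Kinv + (w**2 / _LOG_CHI2_VAR) * (Pm @ Pm.T)
        Llam = np.linalg.cholesky(Lam)
        V = cho_solve((Llam, True), eyeM)
        out.mu[j] = (w / _LOG_CHI2_VAR) * (V @ (Pm @ target))
        out.L[j] = np.linalg.cholesky(V + 1e-12 * eyeM)
    return out


def conjugate_variational_update(params: _Params, X: np.ndarray, y: np.ndarray,
                                 sigma2: float) -> _Params:
    """Exact coordinate-ascent update of q(u) for a constant-noise Gaussian
    likelihood with a single latent function (Q = 1).

    For fixed hyperparameters this is the optimum of the sparse bound, i.e. a
    natural-gradient step of size one; with inducing inputs at the training
    points it reproduces exact GP regression.
    """
    if params.Z.shape[0] != 1 or params.W.shape != (1, 1):
        raise ValueError("conjugate update requires Q = 1, J = 1")
    w = float(params.W[0, 0])
    kern = RBFKernel(np.exp(params.log_ell[0]))
    Z = params.Z[0]
    K = rbf_gram(kern, Z, Z)
    LK, _ = jittered_cholesky(K)
    Kzx = rbf_gram(kern, Z, X)
    Pm = cho_solve((LK, True), Kzx)  # K^-1 K_zx, (M, N)
    eyeM = np.eye(Z.shape[0])
    Kinv = cho_solve((LK, True), eyeM)
    Lam = Kinv + (w**2 / sigma2) * (Pm @ Pm.T)
    Llam = np.linalg.cholesky(Lam)
    V = cho_solve((Llam, True), eyeM)
    mu = (w / sigma2) * (V @ (Pm @ y))
    out = params.copy()
    out.mu[0] = mu
    out.L[0] = np.linalg.cholesky(V + 1e-12 * eyeM)
    return out


# ---------------------------------------------------------------------------
# Prediction containers and user-facing model/results objects


@dataclass
class PosteriorPrediction:
    """Ground-truth and per-annotator noise posterior moments at query points."""

    gt_mean: np.ndarray  # (n,)
    gt_var: np.ndarray  # (n,)
    noise_mean: np.ndarray  # (n, R): E[v_r(x)]
    noise_var: np.ndarray  # (n, R): var[v_r(x)]
    lf_noise_mean: np.ndarray  # (n, R): underlying log-variance LF mean
    lf_noise_var: np.ndarray  # (n, R)


def predict_ground_truth(model: LatentFactorModel, state: VariationalState,
                         Xq: np.ndarray):
    """Posterior mean/variance of the latent ground-truth function at Xq."""
    marg = lf_predictive_marginals(model, state, Xq)
    return marg.means[0], marg.variances[0]


def predict_annotator_variance(model: LatentFactorModel, state: VariationalState,
                               Xq: np.ndarray, r: int):
    """Log-normal posterior moments of annotator r's noise variance at Xq."""
    if not 0 <= r < model.n_latent - 1:
        raise IndexError(f"annotator index {r} out of range")
    marg = lf_predictive_marginals(model, state, Xq)
    return lognormal_moments(marg.means[1 + r], marg.variances[1 + r])


def predict_from_params(params: _Params, standardizer: Standardizer | None,
                        noise_model: str, Xq: np.ndarray) -> PosteriorPrediction:
    """Predict from serialized parameters (used when reloading a saved model)."""
    model, state = params.to_model_state()
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    Xs = standardizer.transform_features(Xq) if standardizer is not None else Xq
    marg = lf_predictive_marginals(model, state, Xs)
    R = params.log_noise.shape[0]
    n = Xs.shape[0]
    if noise_model == "chained":
        R = model.n_latent - 1
        ml, sl = marg.means[1:].T, marg.variances[1:].T
    else:
        ml = np.broadcast_to(params.log_noise, (n, R)).copy()
        sl = np.zeros((n, R))
    gt_mean, gt_var = marg.means[0], marg.variances[0]
    noise_mean, noise_var = lognormal_moments(ml, sl)
    if standardizer is not None:
        gt_mean = standardizer.inverse_target(gt_mean)
        gt_var = standardizer.inverse_target_variance(gt_var)
        noise_mean = standardizer.inverse_target_variance(noise_mean)
        noise_var = noise_var * standardizer.target_std**4
    return PosteriorPrediction(gt_mean, gt_var, noise_mean, noise_var, ml, sl)


class ChainedCrowdGP:
    """Multi-annotator regression model with input-dependent annotator noise.

    Parameters
    ----------
    dataset : MultiAnnotatorDataset
        Features and masked annotator labels.
    n_factors : int, optional
        Number of shared factor GPs Q; defaults to R + 1 (one per latent
        function).
    noise_model : {"chained", "constant"}
        Input-dependent GP log variance per annotator, or a scalar per
        annotator.
    standardize : bool
        Z-score features and pooled labels before fitting (statistics from
        the supplied data); predictions are returned on the original scale
        through the stored standardizer.
    """

    def __init__(self, dataset: MultiAnnotatorDataset, *, n_factors: int | None = None,
                 noise_model: str = "chained", standardize: bool = True):
        if noise_model not in ("chained", "constant"):
            raise ValueError("noise_model must be 'chained' or 'constant'")
        self.raw_dataset = dataset
        if standardize:
            self.standardizer, self.dataset = fit_apply_standardizer(dataset)
        else:
            self.standardizer, self.dataset = None, dataset
        self.likelihood = ChainedLikelihoodConfig(dataset.n_annotators, noise_model)
        self.n_factors = n_factors if n_factors is not None else self.likelihood.n_latent

    @classmethod
    def from_dataframe(cls, df, feature_columns, annotator_columns, **kwargs):
        import pandas as pd

        X = df[list(feature_columns)].to_numpy(dtype=float)
        Y = df[list(annotator_columns)].to_numpy(dtype=float)
        ds = MultiAnnotatorDataset(X, Y, np.isfinite(Y),
                                   list(feature_columns), list(annotator_columns))
        return cls(ds, **kwargs)

    def fit(self, cfg: TrainingConfig | None = None, **overrides) -> "ChainedCrowdGPResults":
        cfg = cfg or TrainingConfig(**overrides)
        params, trace = fit_variational(
            self.dataset.features, self.dataset.labels, self.dataset.observed_mask,
            cfg, self.likelihood, n_factors=self.n_factors, warm_start=True,
            mean_updates=True)
        return ChainedCrowdGPResults(self, params, trace, cfg)


class ChainedCrowdGPResults:
    """Fitted chained crowd GP: predictions, noise surfaces and trust scores."""

    def __init__(self, model_spec: ChainedCrowdGP, params: _Params, trace, cfg):
        self.model_spec = model_spec
        self.params = params
        self.elbo_trace = list(trace)
        self.config = cfg
        self.model, self.state = params.to_model_state()

    # -- internal helpers on the standardized scale -----------------------
    def _transform_X(self, Xq):
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        std = self.model_spec.standardizer
        return std.transform_features(Xq) if std is not None else Xq

    def _noise_marginals(self, Xs):
        marg = lf_predictive_marginals(self.model, self.state, Xs)
        R = self.model_spec.likelihood.n_annotators
        n = Xs.shape[0]
        if self.model_spec.likelihood.noise_model == "chained":
            ml = marg.means[1:].T
            sl = marg.variances[1:].T
        else:
            ml = np.broadcast_to(self.params.log_noise, (n, R)).copy()
            sl = np.zeros((n, R))
        return marg, ml, sl

    # -- public API --------------------------------------------------------
    def predict(self, Xq) -> PosteriorPrediction:
        Xs = self._transform_X(Xq)
        marg, ml, sl = self._noise_marginals(Xs)
        gt_mean, gt_var = marg.means[0], marg.variances[0]
        noise_mean, noise_var = lognormal_moments(ml, sl)
        std = self.model_spec.standardizer
        if std is not None:
            gt_mean = std.inverse_target(gt_mean)
            gt_var = std.inverse_target_variance(gt_var)
            noise_mean = std.inverse_target_variance(noise_mean)
            noise_var = noise_var * std.target_std**4
        return PosteriorPrediction(gt_mean, gt_var, noise_mean, noise_var, ml, sl)

    def predict_ground_truth(self, Xq):
        p = self.predict(Xq)
        return p.gt_mean, p.gt_var

    def predict_annotator_variance(self, Xq, r: int):
        R = self.model_spec.likelihood.n_annotators
        if not 0 <= r < R:
            raise IndexError(f"annotator index {r} out of range for R={R}")
        p = self.predict(Xq)
        return p.noise_mean[:, r], p.noise_var[:, r]

    def trust_scores(self, gamma: float = 0.5) -> np.ndarray:
        """Per-(sample, annotator) trust on the training data (NaN where unobserved)."""
        from .trust import trust_score

        ds = self.model_spec.raw_dataset
        p = self.predict(ds.features)
        T = np.full(ds.labels.shape, np.nan)
        obs = ds.observed_mask
        T[obs] = trust_score(ds.labels[obs],
                             np.broadcast_to(p.gt_mean[:, None], ds.labels.shape)[obs],
                             p.noise_mean[obs], gamma=gamma)
        return T

    def summary(self) -> str:
        ds = self.model_spec.raw_dataset
        lik = self.model_spec.likelihood
        p = self.predict(ds.features)
        lines = []
        lines.append("Chained crowd GP regression results")
        lines.append("=" * 55)
        lines.append(f"Samples: {ds.n_samples}   Features: {ds.n_features}   "
                     f"Annotators: {ds.n_annotators}")
        lines.append(f"Latent functions: {lik.n_latent}   Factors: {self.model.n_factors}   "
                     f"Inducing points: {self.model.n_inducing}")
        lines.append(f"Noise model: {lik.noise_model}   "
                     f"Final ELBO: {self.elbo_trace[-1]:.4f}   "
                     f"ELBO evaluations: {len(self.elbo_trace)}")
        lines.append("-" * 55)
        lines.append(f"{'annotator':>12} {'n labels':>9} {'mean noise var':>15} "
                     f"{'mean trust':>11}")
        T = self.trust_scores()
        for r, aid in enumerate(ds.annotator_ids):
            nr = int(ds.observed_mask[:, r].sum())
            nv = float(np.mean(p.noise_mean[:, r]))
            tv = float(np.nanmean(T[:, r])) if nr else float("nan")
            lines.append(f"{aid:>12} {nr:>9d} {nv:>15.4f} {tv:>11.4f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        std = self.model_spec.standardizer
        blob = {
            "n_annotators": self.model_spec.likelihood.n_annotators,
            "noise_model": self.model_spec.likelihood.noise_model,
            "annotator_ids": self.model_spec.raw_dataset.annotator_ids,
            "feature_names": self.model_spec.raw_dataset.feature_names,
            "params": {k: np.asarray(getattr(self.params, k)).tolist()
                       for k in self.params.keys()},
            "elbo_trace": [float(v) for v in self.elbo_trace],
            "standardizer": None if std is None else {
                "feature_mean": std.feature_mean.tolist(),
                "feature_std": std.feature_std.tolist(),
                "target_mean": std.target_mean,
                "target_std": std.target_std,
            },
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1, sort_keys=True)

    @staticmethod
    def load_params(path):
        """Load the serialized parameter arrays and metadata from JSON."""
        with open(path) as fh:
            blob = json.load(fh)
        params = _Params(*(np.asarray(blob["params"][k]) for k in
                           ("log_ell", "Z", "W", "mu", "L", "log_noise")))
        std = None
        if blob["standardizer"] is not None:
            s = blob["standardizer"]
            std = Standardizer(np.asarray(s["feature_mean"]), np.asarray(s["feature_std"]),
                               s["target_mean"], s["target_std"])
        return blob, params, std
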