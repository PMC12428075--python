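import numpy as np
import pytest

from crowdgp.data import MultiAnnotatorDataset
from crowdgp.kernels import RBFKernel
from crowdgp.likelihood import expected_log_density
from crowdgp.lmc import lf_predictive_marginals
from crowdgp.model import (
    ChainedCrowdGP,
    ChainedLikelihoodConfig,
    TrainingConfig,
    _elbo_and_grads,
    _init_params,
    conjugate_variational_update,
    elbo,
    fit_variational,
    predict_annotator_variance,
    predict_ground_truth,
)
from crowdgp.baselines import exact_gp_posterior
from crowdgp.simulate import make_synthetic_task


def small_problem(rng, N=10, R=2):
    X = rng.normal(size=(N, 2))
    Y = rng.normal(size=(N, R))
    mask = rng.random((N, R)) < 0.8
    mask[0] = True
    return X, Y, mask


def test_elbo_with_no_observations_is_minus_kl(rng):
    X, Y, mask = small_problem(rng)
    mask[:] = False
    Y[:] = np.nan
    ds = MultiAnnotatorDataset(X, Y, mask)
    lik = ChainedLikelihoodConfig(2, "chained")
    p = _init_params(X, TrainingConfig(n_inducing=4), lik, 3, rng)
    p.mu += rng.normal(0, 0.5, p.mu.shape)
    model, state = p.to_model_state()
    val = elbo(ds, model, state)
    from crowdgp.lmc import gaussian_kl
    from crowdgp.kernels import rbf_gram

    kl = sum(
        gaussian_kl(state.means[q], state.cov_sqrts[q] @ state.cov_sqrts[q].T,
                    rbf_gram(model.kernels[q], model.inducing_inputs[q],
                             model.inducing_inputs[q]))
        for q in range(model.n_factors))
    assert val == pytest.approx(-kl, rel=1e-4, abs=1e-6)


def test_fused_objective_matches_reference_elbo(rng):
    """The fused training objective equals the definitional sum of per-pair
    expected log densities minus the KL terms (full batch, scale 1)."""
    X, Y, mask = small_problem(rng)
    Y = np.where(mask, Y, np.nan)
    ds = MultiAnnotatorDataset(X, Y, mask)
    lik = ChainedLikelihoodConfig(2, "chained")
    p = _init_params(X, TrainingConfig(n_inducing=5), lik, 3, rng)
    p.mu += rng.normal(0, 0.5, p.mu.shape)
    fused, _ = _elbo_and_grads(p, X, ds.labels, mask, np.arange(X.shape[0]), 1.0,
                               lik, want_grads=False)
    model, state = p.to_model_state()
    ref = elbo(ds, model, state)
    assert fused == pytest.approx(ref, rel=1e-5, abs=1e-5)


def test_elbo_matches_monte_carlo(rng):
    """Full ELBO on a 10-point toy vs direct sampling of the variational marginals."""
    X, Y, mask = small_problem(rng, N=10, R=2)
    lik = ChainedLikelihoodConfig(2, "chained")
    p = _init_params(X, TrainingConfig(n_inducing=5), lik, 3, rng)
    p.mu += rng.normal(0, 0.5, p.mu.shape)
    val, _ = _elbo_and_grads(p, X, Y, mask, np.arange(10), 1.0, lik, want_grads=False)
    model, state = p.to_model_state()
    marg = lf_predictive_marginals(model, state, X)
    n_mc = 400_000
    total_mean, total_var = 0.0, 0.0
    for n, r in np.argwhere(mask):
        f1 = rng.normal(marg.means[0, n], np.sqrt(marg.variances[0, n]), n_mc)
        fl = rng.normal(marg.means[1 + r, n], np.sqrt(marg.variances[1 + r, n]), n_mc)
        vals = -0.5 * np.log(2 * np.pi) - 0.5 * fl - 0.5 * (Y[n, r] - f1) ** 2 * np.exp(-fl)
        total_mean += vals.mean()
        total_var += vals.var() / n_mc
    from crowdgp.lmc import gaussian_kl
    from crowdgp.kernels import rbf_gram

    kl = sum(gaussian_kl(state.means[q], state.cov_sqrts[q] @ state.cov_sqrts[q].T,
                         rbf_gram(model.kernels[q], model.inducing_inputs[q],
                                  model.inducing_inputs[q]))
             for q in range(model.n_factors))
    mc = total_mean - kl
    assert val == pytest.approx(mc, abs=4 * np.sqrt(total_var) + 1e-4)


def test_full_gradient_against_finite_differences(rng):
    X, Y, mask = small_problem(rng, N=8, R=2)
    lik = ChainedLikelihoodConfig(2, "chained")
    p = _init_params(X, TrainingConfig(n_inducing=4), lik, 3, rng)
    p.mu += rng.normal(0, 0.3, p.mu.shape)
    rows = np.arange(8)
    _, g = _elbo_and_grads(p, X, Y, mask, rows, 1.0, lik)
    eps = 1e-6
    for key in ("mu", "W", "L", "log_ell", "Z"):
        arr = getattr(p, key)
        flat_idx = rng.choice(arr.size, size=min(4, arr.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, arr.shape)
            if key == "L" and idx[-2] < idx[-1]:
                idx = idx[:-2] + (idx[-1], idx[-2])
            p2, p3 = p.copy(), p.copy()
            getattr(p2, key)[idx] += eps
            getattr(p3, key)[idx] -= eps
            v2, _ = _elbo_and_grads(p2, X, Y, mask, rows, 1.0, lik, want_grads=False)
            v3, _ = _elbo_and_grads(p3, X, Y, mask, rows, 1.0, lik, want_grads=False)
            fd = (v2 - v3) / (2 * eps)
            assert getattr(g, key)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_fit_is_deterministic(rng):
    X, Y, mask = small_problem(rng, N=20, R=2)
    cfg = TrainingConfig(n_inducing=8, batch_size=10, max_steps=40, seed=11)
    lik = ChainedLikelihoodConfig(2, "chained")
    p1, t1 = fit_variational(X, Y, mask, cfg, lik)
    p2, t2 = fit_variational(X, Y, mask, cfg, lik)
    assert t1 == t2
    for k in p1.keys():
        np.testing.assert_array_equal(getattr(p1, k), getattr(p2, k))


def test_fit_improves_elbo_on_simulated_data():
    task = make_synthetic_task(120, C=4, seed=5)
    cfg = TrainingConfig(n_inducing=20, batch_size=60, max_steps=150, seed=2)
    lik = ChainedLikelihoodConfig(task.labels.shape[1], "chained")
    _, trace = fit_variational(task.features, task.labels, task.mask, cfg, lik)
    assert max(trace) >= trace[0]
    assert trace[-1] == max(trace)  # best state restored


def test_fit_requires_observations(rng):
    X = rng.normal(size=(5, 2))
    Y = np.full((5, 2), np.nan)
    with pytest.raises(ValueError, match="observed"):
        fit_variational(X, Y, np.zeros((5, 2), bool),
                        TrainingConfig(n_inducing=3), ChainedLikelihoodConfig(2))


def test_conjugate_regime_matches_exact_gp(rng):
    """With inducing points at the training inputs and frozen constant noise,
    the optimized variational posterior reproduces exact GP regression and the
    bound never exceeds the exact log marginal likelihood."""
    N = 50
    X = rng.uniform(-3, 3, size=(N, 1))
    sigma2 = 0.05
    y = np.sin(X[:, 0]) + rng.normal(0, np.sqrt(sigma2), N)
    lik = ChainedLikelihoodConfig(1, "constant")
    p = _init_params(X, TrainingConfig(n_inducing=N), lik, 1, rng)
    p.Z[0] = X.copy()
    p.W[:] = 1.0
    p.log_noise[:] = np.log(sigma2)
    p_opt = conjugate_variational_update(p, X, y, sigma2)
    Xq = rng.uniform(-3, 3, size=(25, 1))
    model, state = p_opt.to_model_state()
    mean, var = predict_ground_truth(model, state, Xq)
    kern = RBFKernel(np.exp(p.log_ell[0]))
    mean_ex, var_ex, lml = exact_gp_posterior(kern, X, y, sigma2, Xq)
    np.testing.assert_allclose(mean, mean_ex, atol=1e-3)
    np.testing.assert_allclose(var, var_ex, atol=1e-3)
    val, _ = _elbo_and_grads(p_opt, X, y[:, None], np.ones((N, 1), bool),
                             np.arange(N), 1.0, lik, want_grads=False)
    assert val <= lml + 1e-6


def test_predictions_delegate_and_noise_positive(rng):
    task = make_synthetic_task(80, C=4, seed=1)
    ds = MultiAnnotatorDataset(task.features, task.labels, task.mask)
    res = ChainedCrowdGP(ds, standardize=False).fit(
        TrainingConfig(n_inducing=15, batch_size=40, max_steps=60, seed=0))
    marg = lf_predictive_marginals(res.model, res.state, task.features[:5])
    gm, gv = res.predict_ground_truth(task.features[:5])
    np.testing.assert_allclose(gm, marg.means[0], atol=1e-12)
    np.testing.assert_allclose(gv, marg.variances[0], atol=1e-12)
    p = res.predict(task.features[:20])
    assert np.all(p.noise_mean > 0)
    assert np.all(p.noise_var >= 0)
    assert np.all(p.gt_var >= 0)
    with pytest.raises(IndexError):
        res.predict_annotator_variance(task.features[:2], r=99)


def test_prior_state_predicts_zero_mean(rng):
    lik = ChainedLikelihoodConfig(2, "chained")
    X = rng.normal(size=(12, 2))
    p = _init_params(X, TrainingConfig(n_inducing=6), lik, 3, rng)
    model, state = p.to_model_state()  # mu = 0, V = K: the prior
    mean, _ = predict_ground_truth(model, state, rng.normal(size=(4, 2)))
    np.testing.assert_allclose(mean, 0.0, atol=1e-10)


def test_annotator_variance_lognormal_values(rng):
    task = make_synthetic_task(60, C=4, seed=2)
    ds = MultiAnnotatorDataset(task.features, task.labels, task.mask)
    res = ChainedCrowdGP(ds, standardize=False).fit(
        TrainingConfig(n_inducing=10, batch_size=30, max_steps=30, seed=0))
    marg = lf_predictive_marginals(res.model, res.state, task.features[:6])
    nm, nv = predict_annotator_variance(res.model, res.state, task.features[:6], 1)
    mu, s2 = marg.means[2], marg.variances[2]
    np.testing.assert_allclose(nm, np.exp(mu + s2 / 2), rtol=1e-12)
    np.testing.assert_allclose(nv, np.exp(2 * mu + s2) * (np.exp(s2) - 1), rtol=1e-10)


def test_results_summary_and_save_roundtrip(tmp_path):
    task = make_synthetic_task(60, C=4, seed=3)
    ds = MultiAnnotatorDataset(task.features, task.labels, task.mask)
    res = ChainedCrowdGP(ds).fit(TrainingConfig(n_inducing=10, batch_size=30,
                                                max_steps=30, seed=0))
    s = res.summary()
    assert "Annotators: 5" in s and "ELBO" in s
    path = tmp_path / "m.json"
    res.save(path)
    from crowdgp.model import ChainedCrowdGPResults, predict_from_params

    blob, params, std = ChainedCrowdGPResults.load_params(path)
    p1 = res.predict(task.features[:7])
    p2 = predict_from_params(params, std, blob["noise_model"], task.features[:7])
    np.testing.assert_allclose(p1.gt_mean, p2.gt_mean, atol=1e-10)
    np.testing.assert_allclose(p1.noise_mean, p2.noise_mean, atol=1e-10)
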