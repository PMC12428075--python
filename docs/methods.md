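# Methods

This note documents the model, the inference scheme, the trust score, the
simulator and the evaluation protocol implemented in `crowdgp`, together with
the numerical choices and known limitations. It describes only what the code
computes; empirical figures are reproduced by `tests/` and
`scripts/acceptance.py`.

## 1. Observation model

Data are `N` samples with features `x_n ∈ R^P` and a partially observed label
matrix `y_nr` from `R` annotators (mask `m_nr`). Each annotation is modelled
as

```
y_nr = f(x_n) + eps_nr,   eps_nr ~ N(0, v_r(x_n)),   v_r(x) = exp(g_r(x)).
```

The ground-truth mean `f` and the per-annotator log noise variances `g_r` are
`J = R + 1` latent functions. They are coupled through a linear model of
coregionalization (LMC): with `Q` independent factor GPs
`u_q ~ GP(0, k_q)`,

```
f_j(x) = Σ_q W[j, q] · u_q(x),        j = 0 .. R,
```

where `f_0 = f` and `f_{1+r} = g_r`. By default `Q = J`, and `W` is
initialized identity-dominant (`W[j, j] = 1` plus `N(0, 0.1)` cross-loadings)
so each latent function starts with a dedicated factor while retaining
learnable correlations between the ground truth and the noise surfaces. Each
factor uses a squared-exponential (RBF) kernel with its own log length-scale;
amplitudes are absorbed into `W`.

A `noise_model="constant"` variant replaces the `R` log-variance functions
with one scalar log variance per annotator; it is used by the homoscedastic
baselines and the conjugate-regime checks.

## 2. Sparse variational inference

Each factor `q` carries `M` inducing inputs `Z_q` with an unwhitened
variational posterior `q(u_q) = N(μ_q, L_q L_qᵀ)` (`L_q` lower triangular).
The induced marginals at an input `x` are Gaussian with

```
mean_q(x) = k_q(x, Z_q) K_q^{-1} μ_q
var_q(x)  = k_q(x, x) − k_q(x, Z_q) K_q^{-1} (K_q − L_q L_qᵀ) K_q^{-1} k_q(Z_q, x)
```

and the latent-function marginals follow by the LMC mixing:
`E[f_j] = Σ_q W[j,q] mean_q`, `Var[f_j] = Σ_q W[j,q]² var_q`.

The ELBO is

```
L = Σ_{(n,r): m_nr} E_q[ log N(y_nr | f_0(x_n), exp(f_{1+r}(x_n))) ]
    − Σ_q KL( q(u_q) || N(0, K_q) ).
```

The per-pair expected log density is closed form. Writing `m1, s1` for the
mean/variance of `f_0(x_n)` and `ml, sl` for those of `f_{1+r}(x_n)`,

```
E[log p] = −½ log 2π − ½ ml − ½ ((y − m1)² + s1) · exp(−ml + sl/2),
```

using `E[exp(−g)] = exp(−ml + sl/2)` for log-normal `exp(g)`. The first and
second moments of the noise variance itself are `E[v] = exp(ml + sl/2)` and
`Var[v] = exp(2ml + sl)(exp(sl) − 1)`; `E[v]` is what prediction and trust
scoring report. Both expressions are verified against Monte-Carlo oracles in
the test suite.

### Optimization

The environment has no automatic differentiation, so all ELBO gradients
(with respect to `μ_q`, `L_q`, `W`, the log length-scales and `Z_q`) are
derived by hand and finite-difference-checked in the tests. Training is:

- **Minibatch Adam** over rows of the label matrix, with the data term
  rescaled by `N / |batch|`. Defaults: learning rate `1e-2`, batch 128,
  `M = 200` inducing points, up to 1000 steps.
- **Full-ELBO monitoring** every 10 steps; the learning rate is halved after
  20 evaluations without improvement (floor `1e-6`), training stops after a
  long plateau, and the best-scoring parameter state is restored at the end.
- **Determinism**: all randomness flows from `TrainingConfig.seed` through a
  single `numpy` generator, so a fit is exactly reproducible.

Plain stochastic gradients on this objective have a well-known failure mode:
the noise functions can absorb the signal (`W → 0`, `v → Var(y)`), a local
optimum the optimizer escapes very slowly. Three closed-form coordinate-ascent
devices remove it:

1. **Warm start.** Before the first step, `q(u_0)` for the ground-truth
   factor is set by an exact conjugate GP-regression update against the
   per-sample averaged labels with a fixed small noise (0.1), so the mean
   function starts near the consensus rather than at zero.
2. **Exact mean-factor update.** For fixed noise functions the likelihood is
   Gaussian in `f_0` with per-pair precision `ρ_nr = exp(−ml + sl/2)`, so the
   optimal `q(u_0)` is available in closed form
   (`Λ = K^{-1} + w² P diag(ρ·) Pᵀ`, `P = K^{-1} K_{ZX}`). It is applied at
   each ELBO evaluation.
3. **Noise-factor refresh.** Squared residuals `(y − m1)² + s1` are, under
   the model, `v_r(x) · χ²₁` to first order; taking logs gives a surrogate
   regression target `t = log((y − m1)² + s1) − E[log χ²₁]` with moment-
   matched variance `π²/2`, where `E[log χ²₁] = log 2 + ψ(½) ≈ −1.27036`.
   Each annotator's dedicated factor gets a conjugate update against `t`.

Updates 2 and 3 are *gated*: a candidate is kept only if the full ELBO does
not decrease, so the procedure remains a valid ascent on the bound. The
surrogate in update 3 is a heuristic accelerator, never the objective.

### Conjugate special case

With one annotator, constant frozen noise, `Q = 1` and the inducing points
placed at the training inputs, the model reduces to exact GP regression: the
conjugate update recovers the exact posterior, and the ELBO equals the log
marginal likelihood up to numerical tolerance. This equivalence (and the
bound `ELBO ≤ LML` away from it) is asserted in the acceptance tests against
a dense Cholesky reference.

## 3. Trust score

Per-annotation trust is

```
T_r(x_n) = exp( −(y_nr − f̂(x_n))² / (2 (2 v̂_r(x_n))^γ) ),   γ = 0.5,
```

with `f̂` the posterior ground-truth mean and `v̂_r = E[v_r(x_n)]` the
posterior mean noise variance. Scores lie in `(0, 1]` and equal 1 at zero
residual. The variance enters *sublinearly* (for `γ < 1`): a locally noisy
annotator is only partially forgiven, so under a calibrated noise model the
expected trust still decreases with the annotator's local noise level
(roughly as `exp(−c · v^{1−γ})`) and average trust ranks annotators by local
competence. At `γ = 1` the exponent is a scaled Gaussian log-likelihood.
Note that the *fully* calibrated alternative `exp(−((y−f̂)²/(2v))^γ)` would
be nearly constant across annotators whenever `v̂` is accurate and is not
used.

Cluster-level diagnostics average trust over (annotator, input-cluster)
cells, compute the within-cluster empirical `R²` of each annotator against a
reference target, and report the Pearson correlation between the two
matrices. Undefined cells (empty, or degenerate denominators) are NaN, never
zero.

## 4. Simulator

`make_synthetic_task(N, C, seed)` draws `C` cluster centers on a circle in
2-D, scatters samples around them (sd `cluster_spread = 0.6`), sets the
ground truth to a smooth sinusoidal function of the inputs, and adds
per-annotator Gaussian noise whose variance is set *per (annotator, cluster)
cell* from a signal-to-noise profile in dB:

```
σ²_rc = P_signal / 10^(SNR_rc / 10),
```

with `P_signal` the empirical variance of the ground truth. The default
profile is 5 annotators × 4 clusters:

```
[[10, 10, 10, 10],     # uniform expert
 [ 6, −3, −3,  7],
 [−3, −3,  8, −3],
 [−3,  7,  4, −3],
 [−3, −3, −3, −3]]     # uniform novice
```

The realized noise matches the requested SNR in distribution; its per-cell
empirical deviation shrinks as `1/√n` and is checked at `n = 10⁵` in the
tests. The profile is deliberately tie-heavy, which caps the attainable
Spearman correlation between estimated trust cells and SNR cells below 1
(the tie-adjusted ceiling for the default profile is ≈ 0.909).

`partition_inputs` clusters arbitrary feature matrices (standardize → PCA or
UMAP embedding → k-means). Because columns are standardized first, a
pure-noise feature carries as much weight as an informative one; clusters
are only meaningful if most features are informative. `make_sensory_fixture`
generates a small sensory-panel-shaped table (bounded 0–10 scores, realistic
missingness) for I/O tests.

**Scope.** The simulator produces Gaussian, cluster-piecewise-constant
annotator noise around a smooth scalar ground truth. It does not model
annotator bias, label censoring/rounding, adversarial raters, or
non-stationary ground truth.

## 5. Baselines and evaluation

- **GPR-AVG**: sparse GP regression on the per-sample mean of the observed
  labels (rows with no labels are dropped with a warning).
- **GPR-GT**: the same regressor fit on the true targets — an oracle upper
  reference, only available in simulation.

Both use the constant-noise engine with the same interleaved conjugate
updates, so comparisons isolate the value of modelling annotator structure,
not optimizer quality.

`run_benchmark` repeats a cluster-stratified 70/30 split, fits all methods
on the training part, and reports MSE / RMSE / MAE / R² on the held-out
part. Significance uses a Friedman omnibus over per-repeat scores followed
by Bonferroni-corrected Wilcoxon signed-rank pairwise tests. With exactly
two methods `scipy`'s Friedman test is undefined; the code substitutes the
exact two-sided sign test on paired differences, which is the two-group
specialization of the Friedman statistic.

## 6. Numerical choices

- Kernel Gram matrices get a `1e-6` diagonal jitter before Cholesky,
  escalating ×10 (up to `1e-2`) if the factorization fails.
- Features and labels are standardized inside the model; predictions and
  reported noise variances are mapped back to the original label scale.
- `L_q` is parameterized directly as a lower-triangular matrix (its strict
  upper triangle is masked); KL terms use Cholesky-based log-determinants.
- Squared residuals in the noise-factor refresh are floored at `1e-12`
  before the log.
- CSV export uses `%.10g` formatting; model state is saved as JSON with
  full-precision floats, so CLI reruns with the same seed are byte-identical.

## 7. Limitations

- The noise surfaces are log-Gaussian and unimodal per annotator; abrupt
  reliability changes are smoothed by the kernel length-scale.
- Annotator *bias* (systematic offset) is not modelled; a biased annotator
  is absorbed partly into noise, lowering their trust rather than correcting
  the bias.
- The ELBO is non-convex; the coordinate-ascent devices make the reported
  optimum robust across seeds at the studied scales, but global optimality
  is not guaranteed.
- The closed-form noise refresh assumes each log-variance function has a
  dominant dedicated factor (identity-dominant `W`); with strongly shared
  factors (`Q < J`) only the gradient path updates the noise surfaces.
- Trust scores depend on the model's own estimates of `f` and `v`; if the
  fit is poor, trust is correspondingly unreliable. The cluster-level
  trust-vs-`R²` correlation is the built-in diagnostic for this.
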