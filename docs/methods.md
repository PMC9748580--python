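# Methods

This note records the model, the variational scheme, and the numerical
choices made in `mglmmvb`, in enough detail to re-derive the implementation.

## 1. Model

Subjects `i = 1..m` are observed on `R` longitudinal markers. Marker `r` of
subject `i` has `n_ir ≥ 0` visits with responses `y_irj`, fixed-effect
covariates `x_irj ∈ R^{p_r}` and random-effect covariates `z_irj ∈ R^{q_r}`.
Conditional on the linear predictor `η_irj = x_irj'β_r + z_irj'u_ir`, the
response follows a canonical-link exponential family

```
p(y | η) = exp{ (yη − b(η)) / σ²_r  +  c(y, σ²_r) }
```

with `b(x) = x²/2` (Gaussian, dispersion `σ²_εr`), `b(x) = eˣ` (Poisson,
`σ² = 1`), or `b(x) = log(1 + eˣ)` (Bernoulli, `σ² = 1`).

The per-subject random effects are stacked `u_i = (u_i1', …, u_iR')' ∈ R^q`,
`q = Σ q_r`, and share a joint distribution `u_i ~ N(0, Σ_R)` — the
off-diagonal blocks of `Σ_R` are what couples the markers.

Priors:

- `β ~ N(0, σ²_β I)` with `σ²_β = 10⁴` by default;
- `Σ_R | a ~ Inverse-Wishart(ν + q − 1, 2ν diag(1/a₁,…,1/a_q))`,
  `a_k ~ Inverse-Gamma(1/2, 1/A_k²)` — this hierarchy gives each standard
  deviation `√(Σ_R)_kk` a marginal half-t(ν) distribution with scale `A_k`,
  avoiding the boundary pathologies of a plain inverse-Wishart. Defaults
  `ν = 2`, `A_k = 10⁴`;
- `σ²_εr ~ Inverse-Gamma(1/2, 1/a_εr)`, `a_εr ~ Inverse-Gamma(1/2, 1/A_εr²)`
  for each Gaussian marker (half-Cauchy marginal on `σ_εr`), `A_εr = 10⁴`.

## 2. Variational approximation

The posterior is approximated by the mean-field factorization

```
q(β, u, Σ_R, a, σ²_ε, a_ε) = q(β, u) q(Σ_R) Π q(a_k) Π q(σ²_εr) q(a_εr)
```

Optimal factor forms follow from coordinate ascent on the evidence lower
bound (ELBO): `q(β,u)` is Gaussian, `q(Σ_R)` inverse-Wishart with scale
`B_q(Σ_R)` and `df = ν + q + m − 1`, and the scalar factors are
inverse-gamma. Non-Gaussian likelihood terms are handled by the working
weights below, so one update cycle is:

1. `(β, u)` Gaussian update (streamlined; Section 3),
2. recompute predictor moments `μ_irj = E_q[η_irj]`, `v_irj = Var_q[η_irj]`,
3. Gaussian residual variances: `B_q(σ²_εr) = μ_q(1/a_εr) + ½ E_q‖y_r − C_r ν‖²`,
   `μ_q(1/σ²_εr) = (N_r + 1) / (2 B_q(σ²_εr))`,
4. auxiliaries: `B_q(a_k) = ν [M_q(Σ_R⁻¹)]_kk + A_k⁻²`,
   `μ_q(1/a_k) = ½(ν + q)/B_q(a_k)`, and analogously for `a_εr`,
5. `B_q(Σ_R) = Σ_i (μ_q(u_i) μ_q(u_i)' + Σ_q(u_i)) + 2ν diag(μ_q(1/a))`,
   `M_q(Σ_R⁻¹) = (ν + q + m − 1) B_q(Σ_R)⁻¹`,
6. ELBO evaluation; stop when `|Δℓ| / (1 + |ℓ|) < 10⁻⁷` (max 500 cycles).

### Cumulant moments under a Gaussian predictor

With `η ~ N(μ, v)` the updates need `E[b'(η)]` and `E[b''(η)]`:

- Gaussian: `E[b'] = μ`, `E[b''] = 1` (exact);
- Poisson: `E[b'] = E[b''] = exp(μ + v/2)` (lognormal mean, exact);
- Bernoulli: no closed form. The logistic function is replaced by an
  eight-component probit mixture `expit(x) ≈ Σ_k p_k Φ(s_k x)` (weights
  non-negative, summing to one), for which the Gaussian smoothing is exact:
  `E[b'] = Σ p_k Φ(s_k μ / √(1 + s_k² v))` and
  `E[b''] = Σ p_k s_k φ(s_k μ / √(1 + s_k² v)) / √(1 + s_k² v)`.
  The mixture is fitted by the package itself (Nelder–Mead over log-scales
  with weights profiled out by non-negative least squares) to max absolute
  error 1.3e-7 on [−10, 10]; a test refits it from scratch. `E[b'']` is
  floored at 1e-12 to keep working weights positive.

The working weights and residuals are `W = E[Σ_ε⁻¹] diag(E[b''])` and
`r = E[Σ_ε⁻¹] (y − E[b'])`, giving the non-Gaussian markers the same
algebraic shape as the Gaussian ones inside the `(β,u)` update.

## 3. Streamlined `(β, u)` update

Let `X` be the stacked fixed-effects design (block-diagonal across markers),
`Z_i` subject i's random-effects design, `C = [X Z]`. The naive update
inverts the `(p + mq) × (p + mq)` matrix `C'WC + blockdiag(σ_β⁻²I, I_m ⊗ M)`
with `M = M_q(Σ_R⁻¹)` — cubic in `m`. The joint precision is block-sparse
(subjects couple only through β), so a block-LDL factorization gives the
exact update at `O(m)` cost:

```
G_i = X_i' W_i Z_i
H_i = (Z_i' W_i Z_i + M)⁻¹                       (q × q, per subject)
S   = Σ_i G_i H_i G_i'
Σ_q(β)  = (X'WX + σ_β⁻² I − S)⁻¹
μ_q(β) += Σ_q(β) (X'r − σ_β⁻² μ_q(β) + Σ_i G_i H_i (M μ_q(u_i) − Z_i'r_i))
Σ_q(u_i) = H_i + H_i G_i' Σ_q(β) G_i H_i
Cov_q(β, u_i) = −Σ_q(β) G_i H_i
μ_q(u_i) += H_i (Z_i'r_i − M μ_q(u_i) − G_i' Δμ_q(β))
log|Σ_q(ν)| = log|Σ_q(β)| + Σ_i log|H_i|
```

Only the blocks needed downstream are stored — `Σ_q(β)`, each `Σ_q(u_i)`
and `Cov_q(β,u_i)`; the `Cov_q(u_i,u_j)` blocks (which are generally
non-zero) never enter the moments, the conjugate updates or the ELBO.
Predictor moments then come from row-wise quadratic forms:
`v_n = x_n'Σ_q(β)x_n + 2 x_n'Cov_q(β,u_i)z_n + z_n'Σ_q(u_i)z_n`.

`fit_naive` implements the dense update and is used by the test suite to
certify, per cycle, that the streamlined path is exact to machine precision
(a guard refuses dense problems above 2000 unknowns). A frozen-variance mode
pins `Σ_R` and `σ²_ε` at user-supplied values; for all-Gaussian models its
fixed point is the classical Henderson mixed-model-equations solution, which
the tests verify to 1e-13.

### ELBO

All terms are kept (no dropped constants): expected log-likelihoods
(Gaussian exact, Poisson via the lognormal mean, Bernoulli
`E[log(1+e^η)]` by 30-point Gauss–Hermite quadrature), Gaussian prior and
entropy of `(β,u)` using the streamlined log-determinant, inverse-Wishart
prior/entropy via multivariate digamma identities, and the inverse-gamma
hierarchies. For all-Gaussian models every coordinate update is exact
conditional conjugate ascent, so the ELBO is provably non-decreasing — the
suite checks monotonicity across random instances. For mixed families the
probit-mixture weights make each step an approximation to the exact
coordinate update; monotonicity is not guaranteed in theory but holds in all
tested instances.

## 4. Synthetic data generator

`simulate_dataset` draws, per subject, a visit count `n_i ~ Uniform{5,…,10}`,
a shared time covariate `x_ij = (j−1)/(n_i−1) ∈ [0,1]`, random effects
`u_i ~ N(0, Σ_R)` (Cholesky), and responses from each marker's family. Two
built-in designs mirror a realistic biomarker panel:

- **Design 1** (`scenario_truth(1)`): three Gaussian markers, random
  intercept and slope each (`q = 6`),
  `β = (0.68, −0.95), (−2.50, 0.12), (0.45, 1.21)`,
  `σ²_ε = (0.1, 0.25, 0.15)`, and a full 6×6 `Σ_R` with leading entry 2.58
  and substantial cross-marker correlation.
- **Design 2** (`scenario_truth(2)`): same coefficients and `Σ_R`, but
  marker 2 is Poisson (log link) and marker 3 Bernoulli (logit link).

The generator emulates unbalanced visit counts and (optionally, via
`missing_rate`) missing-at-random response dropout. It does *not* emulate
informative dropout, measurement-error covariates, or non-canonical links.
Returned alongside the table are the true `u_i`, so tests can validate the
generator conditionally (e.g. binned `P(y=1|η)` against `expit(η)`).

## 5. Accuracy diagnostics

`accuracy_score(q, ref)` implements the integrated-absolute-error score
`100 (1 − ½∫|q*(θ) − p̂(θ)| dθ)` — 100 for identical densities, 0 for
disjoint supports. Sample inputs are smoothed with a Gaussian KDE whose
bandwidth is a two-stage direct-plug-in (Sheather–Jones family) estimate;
analytic inputs (frozen distributions, callables) are evaluated directly.
The integral is a trapezoid rule on the union of two local grids (one per
support, padded by three bandwidths), which stays accurate when supports are
far apart. `q_marginals` exposes the fitted factors as scipy frozen
distributions (Gaussian for coefficients, inverse-gamma for variances and
`Σ_R` diagonals, seeded inverse-Wishart Monte Carlo for off-diagonals) so
they can be scored against reference MCMC draws.

## 6. Numerical choices and limitations

- All per-subject loops are vectorized: segment sums via `np.add.reduceat`
  with a zero-pad sentinel (handles subjects with zero rows for a marker),
  batched Cholesky factorizations for the `H_i`, and einsum row-wise
  quadratic forms.
- Symmetric-positive-definite inverses use Cholesky; failures raise
  `NumericalFailure` naming the offending block, and `check_invariants()`
  re-validates every stored covariance.
- Problem sizes: the streamlined path is linear in `m` and cubic only in
  `p` and `q`; `m = 10⁴` subjects with `q = 6` fits in seconds. The dense
  reference is for testing and refuses more than 2000 unknowns.
- Known behavior: posterior SDs for the Bernoulli marker are mildly
  underestimated relative to MCMC (a generic property of Gaussian
  variational approximations to logistic likelihoods); point estimates at
  the tested design sizes are unbiased within Monte-Carlo resolution.
- Convergence is assessed on the ELBO only; for frozen-variance mode (no
  full ELBO defined) the driver monitors the max-abs change of the mean
  parameters.
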