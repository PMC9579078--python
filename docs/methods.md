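# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the bundled synthetic-data tests can show. It is written for
users who need to know exactly what the package computes.

## Models and estimation

### Rasch model, conditional ML

For dichotomous items the Rasch model gives
P(u_ij = 1 | θ_i, b_j) = exp(θ_i − b_j) / (1 + exp(θ_i − b_j)).
Conditioning on the raw score r_i eliminates θ_i: with easiness
ε_j = exp(−b_j), the conditional likelihood of a response pattern is
∏_j ε_j^{u_ij} / γ_{r_i}(ε), where γ_r is the order-r elementary symmetric
function (ESF). ESFs and their first two partial derivatives are computed by
the summation recursion (all intermediates positive; derivatives via
leave-one-out and leave-two-out recursions rather than the unstable
difference algorithm). The conditional log-likelihood is maximized by Newton
iterations with analytic gradient and Hessian, stopping when the score
sup-norm falls below 1e-8 (step halving guards the ascent). Identification:
item 1's difficulty is fixed at 0, so the P = J − 1 free parameters are
b_2 … b_J.

Persons with raw score 0 or J have constant conditional likelihood. They are
retained in N — their score rows are zero — so that row indices stay aligned
with the covariate vector; dropping them would silently change the process
time scale.

### 1PL / 2PL / GPCM, marginal ML

The 2PL in slope/intercept form is
P(u_ij = 1 | θ) = exp(a_j θ + d_j) / (1 + exp(a_j θ + d_j)); the 1PL
constrains all slopes equal. The GPCM is the adjacent-category logistic
model: category k of an item with K + 1 categories has log-numerator
k·a_j·θ + Σ_{v≤k} d_jv (empty sum for k = 0), normalized by log-sum-exp. The
intercepts enter cumulatively, so a two-category GPCM item *is* a 2PL item —
the dichotomous case collapses exactly.

The latent trait is integrated out against N(0, 1) on a Gauss–Hermite grid
with 61 nodes (configurable). 61 nodes keep posterior moments stable out to
|θ| ≈ 7 trait SDs, far beyond where response patterns carry information, and
make the quadrature error negligible relative to sampling error. E-step:
posterior node weights per person (log-space throughout). M-step: per-item
weighted logistic / adjacent-category maximization (BFGS with analytic
gradients on expected counts pooled over group grids); for the 1PL a joint
maximization over the shared slope and all intercepts.

**Impact.** With a grouping covariate, each group g gets its own
N(μ_g, σ_g²); the reference group (first label encountered) is fixed at
N(0, 1) for identification and the other groups' means and variances are free
parameters, updated in the M-step from posterior moments, with the group grid
rescaled to μ_g + σ_g · nodes each iteration. Group variances are weakly
identified when items are few: with 5 items and N = 1000 the ML estimate of a
variance whose true value is 1.0 can land at 1.3 (verified against a direct
maximizer of the same likelihood — the EM finds the optimum; the optimum
itself is noisy). Recovery tests therefore use 10 items.

**Convergence.** EM stops when the largest absolute parameter change drops
below `tol` (default 1e-6) or after `maxit` iterations (default 500), in
which case a warning is emitted and `converged=False` is recorded — the fit
is still returned. The 1e-6 default is deliberately tighter than the common
1e-5: the score column sums at the stopping point scale with the parameter
change (≈ 1.4e-4 at 1e-5, ≈ 2e-5 at 1e-6 in our N = 200 benchmarks), and the
fluctuation tests assume the first-order condition holds to high accuracy.
Impact fits converge slowly (EM's usual behavior for variance parameters);
`maxit` of 2000–5000 is recommended there. The marginal log-likelihood is
recorded per iteration and is non-decreasing (up to grid-rescaling effects of
order 1e-8).

**Missing data** are rejected at load. Supporting missingness would change
every score formula (the per-person gradient would run over observed items
only) and is out of scope.

## Scores

Case-wise score contributions are computed analytically:

* CML Rasch: entry (i, j) is π_{r_i j} − u_ij, the conditional expectation of
  the response given the raw score (an ESF ratio) minus the observed
  response.
* MML slope: Σ_q p_iq · θ_q · (u_ij − Ē_j(θ_q)) on the fit's quadrature grid,
  where p_iq are posterior node weights and Ē_j the expected category; the
  intercept/threshold scores replace the residual with exceedance indicator
  minus exceedance probability. The 1PL slope column is the sum of the
  item-wise slope integrals (chain rule on the equality constraint).
* Impact parameters: posterior-moment form, s_μ = (E_post[θ] − μ_g)/σ_g² and
  s_{σ²} = (E_post[(θ−μ_g)²] − σ_g²)/(2σ_g⁴), nonzero only for persons in
  group g. This is the derivative of the *exact* marginal likelihood
  evaluated by quadrature; it differs from the derivative of the
  quadrature-approximated likelihood (which would also move the grid) by
  quadrature error — up to ~1e-3 per entry in stress tests with large group
  variances, ~1e-7 in well-conditioned fits. The moment form is used because
  the EM fixed point satisfies exactly these moment conditions, so the impact
  score columns sum to zero at convergence, which the fluctuation process
  requires.

Every analytic score path is validated in the test suite against central
finite differences of the per-person log-likelihood (step 1e-5, absolute
tolerance 1e-5 for item parameters).

The covariance of the contributions is estimated by the outer product of
gradients, Î = SᵀS/N — no second derivatives needed, and it matches the
standardization the fluctuation theory assumes. Its inverse square root is
taken by symmetric eigendecomposition and **fails hard** (with a pointer to
parameter-subset testing) when an eigenvalue falls below 1e-10 times the
largest: a rank-deficient Î signals an identification problem, and ridging it
would silently distort every statistic downstream.

By default the tested parameter set is the item parameters; the impact
means/variances are computed and stored but excluded from the test (they
describe the trait distribution, not measurement), and Î is computed on the
tested subset only. Passing `pars` explicitly (or
`include_impact_pars=True`) overrides this.

## The fluctuation process and the statistics

Respondents are sorted by the covariate (stable sort; ties grouped). The
process is only evaluated at boundaries between *distinct* sorted covariate
values — inside a tie block the ordering is arbitrary, and a statistic that
depended on it would not be well defined. Row 0 and row N of the cumulative
process are zero vectors (the MLE identity), which the tests assert.

* **maxLM** maximizes ‖B(t)‖²/(t(1−t)) over admissible boundaries inside the
  trim window, default (0.10, 0.90). The window is configurable because
  published statistics computed by other software may use a different
  internal default.
* **maxLMo** evaluates the same functional at the m − 1 ordered-level
  boundaries (no trimming — the cut set is already finite).
* **LMuo** sums ‖standardized within-level score sum‖² · N/n_l over levels;
  under the null this is χ² with P(m − 1) degrees of freedom.
* **DM** is the maximum absolute entry of the process.

**p-values.** LMuo is analytic (χ²). maxLM and maxLMo p-values are Monte
Carlo: the limiting P-dimensional Brownian bridge is simulated on the
*observed* boundary grid (default 50,000 replications) and the functional's
null sample compared with the observed statistic; seed and replication count
are recorded in the result. Null samples are cached on (grid, P, reps, seed),
so a simulation study whose replications share a boundary grid pays the
simulation cost once — equivalent to a fixed Monte-Carlo critical value. The
DM p-value uses the Brownian-bridge boundary-crossing series
2Σ_{k≥1}(−1)^{k+1}exp(−2k²c²) (100 terms) per component, combined across the
P asymptotically independent standardized components as 1 − (1 − p₁)^P, and
is evaluated at the continuity-corrected level c + 0.5826/√N: the statistic
is a maximum over an N-point grid, not a continuous-time sup, and the
uncorrected series is visibly conservative (≈ 0.02 too large at N = 1000,
confirmed against a 50,000-replication grid simulation). The correction
constant is the Broadie–Glasserman discrete-barrier shift ζ(1/2)/√(2π).

Pairing rules are enforced: LMuo needs an unordered covariate, maxLMo an
ordered one, maxLM/DM a continuous one (an ordered covariate may be passed to
maxLM/DM, which then uses its level boundaries as the time grid; the default
pairing for ordered covariates is maxLMo).

## The synthetic-data generator

The generator emulates the structure of typical questionnaire datasets:
binary or 5-category Likert-type responses, a numeric covariate (e.g. a trait
anger score), categorical covariates (e.g. gender; an ordered area variable
with levels rural/suburban/urban), group impact on the latent trait, and DIF
planted in chosen item parameters. Two DIF forms are supported: a shift of
size δ for an affected subsample (upper covariate half, or chosen levels —
the classic two-regime picture) and a linear drift in the standardized
covariate (the minimal continuous extension). The truth record plus the
covariate table reconstructs every per-person item parameter exactly
(round-trip tested).

What it does **not** emulate: real response styles (midpoint/extreme
responding), local dependence between items, missing responses, guessing
(no 3PL), multidimensional traits, or nonlinear DIF shapes. Passing
calibration and power tests on these data therefore demonstrates that the
machinery is correct under the assumed models, not that the models fit any
particular real dataset.

Default study conditions used by the acceptance checks: DIF-free Rasch data
with N = 500, J = 10, 500 replications for size; DIF shifts δ ∈ {0, 0.4, 0.8}
on one item for power; N = 200, J = 5 for score-gradient verification;
N = 2000 for 2PL recovery. Monte-Carlo p-values inside studies use 10,000–
20,000 replications with a fixed seed (the cached-critical-value setup).

## Reproducing the published questionnaire analyses

Two published analyses can be reproduced once their datasets (distributed
with the R package `psychotools`, not vendored here) are exported to CSV:

```r
# Rscript, with psychotools installed
data("VerbalAggression", package = "psychotools")
write.csv(as.data.frame(VerbalAggression$resp2),
          "data/verbal_aggression_resp2.csv", row.names = FALSE)
write.csv(data.frame(anger = VerbalAggression$anger,
                     gender = VerbalAggression$gender),
          "data/verbal_aggression_covariates.csv", row.names = FALSE)
data("ConspiracistBeliefs2016", package = "psychotools")
write.csv(as.data.frame(ConspiracistBeliefs2016$resp),
          "data/conspiracist_resp.csv", row.names = FALSE)
write.csv(data.frame(area = ConspiracistBeliefs2016$area,
                     gender = ConspiracistBeliefs2016$gender),
          "data/conspiracist_covariates.csv", row.names = FALSE)
```

With the files in `data/`, the reproduction test
(`tests/test_acceptance.py::test_reproduces_published_worked_examples`) runs
the Rasch/CML analysis of verbal-aggression items 1–6 (maxLM along anger,
LMuo along gender) and the GPCM analyses of the conspiracist-beliefs items
(maxLMo along area and LMuo along gender, each with impact modeled on the
tested covariate) and compares the four statistics with their published
values at 1% relative tolerance. The test fails with an explanatory message
when the files are absent rather than passing vacuously. The loader reports
N as found in the export (the source documentation gives slightly different
respondent counts in different places). Note the GPCM threshold sign/shift
convention of other software is not fully published; the 1% tolerance is
meant to absorb optimizer and convention differences, and the maxLM trim
window is exposed because the published statistic's window is unstated.

## Known limitations

* No 3PL/4PL, graded response, nominal, rating-scale/partial-credit via CML,
  or multidimensional models.
* OPG is the only covariance estimator (no observed/expected information or
  sandwich variants).
* The DM component-independence combination is asymptotic; for very small N
  and strongly correlated parameters the Monte-Carlo functionals (maxLM) are
  preferable.
* Impact modeling assumes normal group distributions; CML (which needs no
  distributional assumption) is available only for the Rasch model.
* Anchor selection and effect-size measures for flagged items are out of
  scope; the tests localize DIF only through parameter subsets and the
  recorded peak location.
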