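# Methods

## Model

A methylation observation for individual `i`, CpG `j`, age `t` (decimal
years) is

    y_ij(t) = mu0(t) + f_i(t) + g_j(t) + eps_ij(t)

with `mu0 ~ GP(m0, k_theta0)` shared by the cohort, `f_i ~ GP(0, k_thetaf)`
per individual, `g_j ~ GP(0, k_thetag)` per CpG, and i.i.d. Gaussian noise
`eps` with variance `sigma^2`.  All kernels are squared exponential
(variance in beta² units, lengthscale in years).  The model assumes
additivity on the beta scale and stationarity of all three processes; it
does not model cross-CpG covariance beyond the shared mean structure, nor
array-level artefacts (probe failure, batch effects).

Only the CpG-level mean `m_j = mu0 + g_j` is needed for prediction, so the
common and CpG-specific components are never separated: `m_j` has prior
`GP(m0, k_theta0 + k_thetag)` and is conditioned, per CpG, on all series of
that CpG.  This keeps the E-step closed-form and matches what per-CpG mean
curves with credible bands display.  A consequence is that `theta0` and
`thetag` enter the per-CpG likelihood only through their sum and are not
separately identifiable; both are reported, and with the symmetric default
initialization the optimizer keeps them equal.

Individual series enter with observation covariance
`k_thetaf(t_i, t_i) + sigma^2 I` at the individual's own collection ages.
Within a CpG this is the exact marginal law; across CpGs it treats the
individual process as independent per series, which discards the cross-CpG
coupling through `f_i`.  Per-series marginals — and therefore per-point
forecasts and their credible intervals — are unaffected by this choice.

## Estimation

Hyperparameters are estimated by EM:

- **E-step.**  Exact per-CpG Gaussian hyper-posteriors of `m_j` on the
  pooled grid (the sorted union of all training ages).  Computed in the
  conditioning (covariance) form: only the observation covariance
  `S = Kp[obs, obs] + blockdiag(k_thetaf + sigma^2 I)` is factorized.  `S`
  is kept well-conditioned by its noise floor, whereas the prior precision
  on a dense grid under a smooth kernel is numerically singular — the
  precision-form update is avoided for exactly that reason.  Posterior
  covariance log-determinants use the conditioning identity
  `logdet C = logdet Kp + logdet D − logdet S`.
- **M-step.**  L-BFGS-B ascent of the expected complete-data
  log-likelihood (quadratic terms plus a trace-of-covariances term) over
  log-scale parameters, bounded to [−15, 6].  Gradients are finite
  differences with step 1e-5: the default square-root-of-machine-epsilon
  step is smaller than the objective's factorization-jitter noise and can
  stall the optimizer.  If the optimizer fails to improve, the previous
  hyperparameters are kept (ascent is never violated).
- **Objective trace.**  The fit traces the evidence lower bound — expected
  complete-data log-likelihood plus hyper-posterior entropy — which equals
  the exact log marginal likelihood after each E-step and is non-decreasing
  when both steps are exact/ascent; a decrease beyond numerical slack
  raises an error rather than being silently accepted.  The expected
  complete-data log-likelihood alone (what the M-step maximizes) is not
  guaranteed monotone across E-steps, which is why the ELBO is the traced
  quantity.
- **Convergence.**  Relative ELBO change below `tol` (default 1e-3) or
  `max_iter` (default 25) iterations.  Fits are deterministic: the
  initialization is data-driven, not random.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| prior mean `m0` | grand mean of training betas | betas live in [0, 1]; a zero prior mean would bias extrapolation; per-CpG empirical means or an explicit constant are config options |
| sharing | one `thetaf` for all individuals, one `thetag` for all CpGs | four visits per series cannot identify per-entity kernels; `sharing="specific"` enables them for small cohorts |
| noise | single shared `sigma^2` | per-series noise is unidentifiable from four points; `noise_mode="per_cpg"` available |
| init | kernel variance = empirical beta variance, lengthscale = 2 y, `sigma^2` = 10% of empirical variance | over-dispersed start; EM shrinks components |
| jitter | 1e-8 × mean diagonal, escalating ×10 to 1e-4, then error | four-visit grids under smooth kernels are near-singular |

Duplicate (individual, CpG, age) records are rejected at load rather than
averaged — a duplicate usually signals an upstream join error.

## Forecasting

The forecast for one series evaluates the CpG mean hyper-posterior on the
union of observed and target ages (extending off the pooled grid by
standard GP conditioning of the mean process on its stored grid values —
exact on the grid, reverting to the prior far away), forms the joint
covariance `C_hat + k_thetaf + sigma^2 I` with the mean process integrated
out, and conditions on the individual's observed betas.  With no
observations the forecast is the prior predictive.  Predictive variance is
monotone beyond the last observation and converges to the mean-process
prior plus individual-process and noise variance.

Forecast means are not clamped to [0, 1]: the Gaussian is reported as-is.
When sampling through clock transforms, optional clamping of sampled betas
is available (`clamp=True`) and is recommended when coefficients are large,
since betas are proportions; the default is off.

## Epigenetic age

The clock transform `age = (adult_age + 1) exp(intercept + c^T x) − 1`
(`adult_age` = 20 by convention) is the child-range inverse of the
log-linear age warp used to train elastic-net clocks; the piecewise-linear
branch for ages above `adult_age` is deliberately out of scope (the target
regime is pediatric).  The intercept is held explicitly, outside the
coefficient vector.  Monte-Carlo propagation draws beta vectors
independently across CpGs — the additive model induces cross-CpG posterior
correlation only through the integrated-out shared mean — with 10,000
samples by default, enough that the MC standard error of the mean is far
below the predictive SD.  No proprietary clock coefficients ship with the
package; the CSV loader accepts published coefficient tables
(`cpg_id,coefficient` with an `(Intercept)` row), and toy clocks are
generated for testing.

Age acceleration is the OLS residual of epigenetic on chronological age;
a constant chronological-age design is rejected as degenerate.

## Evaluation

RMSE is computed per individual-CpG series and aggregated as mean (SD)
across series.  CIC95 is the percentage of held-out observations inside
`mean ± 1.96 sd`; with one held-out point per series the per-series values
are 0 or 100 and their mean equals the pooled coverage.  Intervals are
Gaussian-predictive, not quantile-based.  The mixed-linear baseline is the
minimal reading of a mixed model here — random intercepts per individual
and per CpG (no random slopes), fitted by REML via crossed variance
components, falling back to pooled OLS with a warning if the mixed fit
fails.  The CpG-mean baseline is leave-one-out: the target individual's
own final value is excluded.

## Synthetic cohorts

The simulator draws from the model itself on a four-visit schedule
emulating an early-childhood cohort: visits at 0.26, 0.76, 4.05 and 6.05
years with per-individual Gaussian jitter (SD 0.02/0.02/0.09/0.10 y), so
every individual has exact, distinct collection ages.  Default generative
hyperparameters: mean-process variance 0.015 and CpG-process variance
0.010, both with 3-year lengthscales; individual-process variance 0.005
with a 1.5-year lengthscale; noise variance 0.001 (SD ≈ 0.03 beta units,
typical array-level noise); prior mean 0.5.

Raw latent sums are mapped into [0.05, 0.95] by one global affine rescale.
Affinity preserves Gaussianity, so the cohort remains exactly model-true
with recorded effective hyperparameters (variances scale with the square
of the slope; lengthscales are untouched) — this is what makes
parameter-recovery and calibration tests well-posed.  A logistic squash is
available for realism experiments and is excluded from recovery
assertions.  What the simulator does **not** emulate: probe failures and
detection-p-value missingness, batch and cell-composition effects,
non-Gaussian beta-value marginals near the boundaries, and real clock
coefficients.  Passing tests therefore demonstrate correctness of the
inference machinery under the stated model, not robustness to array
artefacts.

## Problem sizes

Test and acceptance runs use desk-scale cohorts chosen as the package's
own working sizes: 20×10 (individuals × CpGs) for unit-level fits and
parameter recovery (10 seeds), 40–60 training and 50–300 test individuals
× 20 CpGs for interval-calibration runs, 10 replicates of 20/15 × 8 for
the baseline-ordering comparison, and a 188-individual × 368-CpG panel for
the batch-forecast bookkeeping check (69,184 forecasts).  Calibration
cohorts deserve a note: forecast errors are correlated within an
individual (the individual process is shared across their CpGs), so
coverage estimates have an effective sample near the number of test
individuals, not the number of held-out points; the reproduction script
uses 300 test individuals to keep that sampling error near one point.

## Known limitations

- `theta0`/`thetag` are reported separately but only their sum is
  identified (see above).
- Shared `sigma^2` is a modelling choice, not an estimate of per-series
  noise; users with replicate assays may prefer `noise_mode="per_cpg"`.
- The E-step conditions each CpG's mean on all series of that CpG;
  prediction for an individual uses only that individual's series at the
  target CpG (no cross-CpG transfer at prediction time).
- `sharing="specific"` grows the M-step dimension linearly with cohort
  size and relies on finite-difference gradients; it is practical only for
  small cohorts.
- Forecast Gaussians can place mass outside [0, 1] near the boundaries;
  interval clipping is left to the user, clamping is available in the
  sampling path.
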