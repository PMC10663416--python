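# Methods

This document defines the statistical model implemented by `aifcount`,
the construction of the exposure offsets, the smoothing and estimation
machinery, the synthetic data generator, and the package's known
limitations.

## 1. The count model

Every blood sample — whether a one-second bin from the autosampler
(ABSS) or a manually drawn tube counted in a well counter — yields a
recorded count `y_i`. The model is a log-link count regression

```
y_i ~ Poisson(mu_i)                          (psi = 0)
y_i ~ NegBin(mu_i, psi),  Var = mu_i + psi * mu_i^2     (psi > 0)

log mu_i = log tau_i + log f(t_i) [+ b * abss_i]
```

`f(t)` is the arterial plasma input function expressed as a count rate
per unit exposure, `tau_i` is a known per-sample exposure offset
(Section 2), and `abss_i` is an indicator for autosampler samples whose
coefficient `b` absorbs a multiplicative between-detector calibration
bias; `exp(b)` is reported as the ABSS bias factor.

The negative binomial is parameterized by the dispersion `psi` so that
`psi -> 0` recovers the Poisson exactly; internally the Poisson branch
is used whenever `psi < 1e-7` to avoid loss of precision in the
negative-binomial log-gamma terms. `psi` is estimated by profiling:
for each candidate `log psi` the penalized model is refitted and the
smoothing-parameter criterion (Section 4) is minimized jointly over
`(log sp, log psi)`.

## 2. Exposure offsets

The offset for sample `i` is a product of physically interpretable
factors:

```
tau_i = duration_s * volume_mL * exp(rho * volume) * 2^(-t_i / T_half)
        * dispersion_i * bpr_i * (1 / parent_fraction_i)
```

* **duration, volume** — counting time and sample volume.
* **volume calibration** `exp(rho * volume)` — well-counter geometric
  efficiency varying with fill volume.
* **decay** — radioactive decay between injection and counting,
  half-life `T_half` (default 20.36 min, carbon-11).
* **dispersion** — ABSS-specific: the sampling line smears the true
  input by an exponential kernel (Section 3). The offset component is
  the ratio `uncorrected / corrected` at each ABSS time; manual samples
  and samples after the ABSS cutoff get exactly 1.
* **blood-to-plasma ratio (bpr)** — converts the plasma-referenced
  `f(t)` to whole-blood count rate for detectors that see whole blood;
  estimated from paired whole-blood/plasma manual samples (log-linear
  in time, with a constant fallback and a warning when the pairs do not
  support a slope).
* **parent fraction** — fraction of plasma activity that is
  unmetabolised tracer, modelled as a sigmoid in time and fitted to the
  parent-fraction measurements; enters inverted because `f(t)` is the
  parent (metabolite-corrected) input.

Because every factor multiplies the Poisson mean, samples are
automatically weighted by the information they carry: a 1-second
low-volume ABSS bin influences the fit far less than a long-counted
manual tube, with no ad-hoc weights.

## 3. External dispersion correction

The ABSS measures the convolution of the true input with a
monoexponential transport kernel `(1/kappa) exp(-t/kappa)` (default
`kappa` = 2.5 s). The inverse relation

```
I_true(t) = kappa * dI_meas/dt + I_meas(t)
```

is applied on the uniform 1 Hz grid with central differences.
Differentiation amplifies counting noise, so `build_dispersion_table`
smooths the measured rate with a 31 s moving average before
differentiating, bounds the corrected rate to within a factor 5 of the
measured rate, and smooths the resulting correction *factor* over the
same window — the true factor varies slowly away from the bolus peak,
so this suppresses noise without biasing the descent (verified in the
test suite: RMS error of the estimated factor < 0.05 on the descent).
The forward operation used by the simulator is a discrete convolution
with an exactly unit-sum kernel, so mass is conserved and the
round-trip (forward then correct) is accurate to well under 1% RMS of
the curve maximum on the interior of the grid.

## 4. Estimation machinery

### PIRLS

All models are fitted by penalized iteratively reweighted least squares
(penalized Fisher scoring with step halving, gradient tolerance 1e-9).
The design is assembled from blocks (parametric columns, spline bases),
each block contributing a penalty `sp_j * S_j`.

For shape-constrained blocks the spline coefficients are a nonlinear
transform of working parameters (Section 5) and the chain rule is
applied each iteration. The Newton system additionally includes the
exact curvature of the transform — the diagonal term `-(J^T X^T u)` on
the step parameters, clipped at zero to keep the Hessian positive
definite. Without this term Fisher scoring can stall on strongly
curved transforms (observed: 200 iterations with the gradient norm
stuck around 5, fixed by the exact term).

### Smoothing-parameter selection (LAML)

Smoothing parameters maximize the Laplace-approximate marginal
likelihood

```
LAML = l_p(beta_hat) + 1/2 log|S_lambda|_+ - 1/2 log|H| + (M_p/2) log(2 pi)
```

where `l_p` is the penalized log-likelihood at the PIRLS optimum, `H`
the penalized Hessian, and `M_p` the total penalty null-space
dimension. `log|S_lambda|_+` (the log pseudo-determinant of the total
penalty) is computed **blockwise**: each block's penalty eigenvalues
are thresholded relative to that block's own largest eigenvalue, and
`rank_j * log sp_j` added per block. A single threshold on the
assembled matrix misclassifies the rank of lightly penalized blocks
when smoothing parameters differ by orders of magnitude, flattening the
criterion in some directions. The criterion is optimized by
Nelder-Mead over `log sp` (plus `log psi` for the negative binomial).

### Parametric model

The tri-exponential descent `f(t) = sum_k A_k exp(-gamma_k t)` is
fitted as a nonlinear Poisson regression on the log scale with an
analytic gradient (L-BFGS-B over log parameters), the ABSS bias as a
linear column, and starting values from classical curve stripping.
Component ordering `gamma_1 > gamma_2 > gamma_3` is enforced by sorting.

### Model comparison and diagnostics

Models are compared by AIC computed with the effective degrees of
freedom (trace of the influence matrix) rather than raw parameter
counts. Randomized quantile residuals (uniform-randomized within the
discrete CDF step, then probit-transformed) are exactly standard normal
under a correctly specified model; the package reports their SD,
Kolmogorov–Smirnov test against N(0,1), and Q-Q slope. The Pearson
dispersion statistic is provided as a quick overdispersion check.

## 5. Spline bases

* **B-splines** — standard Cox–de Boor bases with quantile knots.
* **SCOP (monotone non-increasing)** — working parameters
  `(beta_1, delta_2, ..., delta_k)` with
  `beta_j = beta_1 - sum_{l<=j} exp(delta_l)`: coefficients are
  strictly decreasing for *every* finite working value, so
  monotonicity is structural, not a soft constraint. The penalty is a
  first-difference penalty on the `delta` (log-step) scale.
* **Thin-plate regression splines (1-D)** — cubic radial basis
  `|x - x_j|^3` at quantile knots, eigen-truncated, with an exact
  `{1, x}` null space; used on linear or logarithmic time.
* **Factor smooths** — per-examination copies of a TPS basis arranged
  block-diagonally with a shared smoothing parameter and a full-rank
  penalty (deviations are shrunk all the way to zero when the data do
  not support them). This is the random-curve term of the hierarchical
  model: a shared population smooth plus per-exam deviation smooths,
  which is what lets an examination reduced to two manual samples
  borrow its curve shape from the population.

## 6. Synthetic data generator

The generator mimics a dynamic PET blood protocol:

* continuous ABSS sampling at 1 Hz for 10 min (600 bins) plus a
  pre-injection background segment (default 30 s, 1 cps background);
* 14 manual draw times out to 90 min, counted as whole-blood and plasma
  pairs; parent-fraction measurements at 8 times;
* true plasma curve: linear rise to a bolus peak at 0.7 min, then a
  tri-exponential descent with default amplitudes (4000, 800, 150) and
  rates (3, 0.3, 0.03) per minute;
* whole-blood counts scaled by a time-varying blood-to-plasma ratio;
  parent fraction follows a decreasing sigmoid;
* the ABSS stream is forward-dispersed (`kappa` = 2.5 s), decay acts on
  all samples, and ABSS counts carry a multiplicative bias (default
  1.10) relative to the well counter;
* counts are drawn Poisson, or negative-binomial with dispersion `psi`
  via a gamma-Poisson mixture.

Every simulated examination returns a ground-truth ledger (curve,
per-sample expected counts, nuisance functions) so that recovery can be
scored exactly, and `true_offsets` reconstructs the generator's own
exposure offsets for known-offsets experiments.

## 7. Limitations

* **Fast-component identifiability.** With descent-only data and a
  small ABSS sample volume the fastest exponential `(A_1, gamma_1)`
  carries little Fisher information; its estimates are highly variable
  even when the slow components are recovered to a few percent. This
  is a property of the design, not the estimator.
* **Offsets treated as known.** Blood-to-plasma ratio, parent fraction
  and the dispersion table are estimated from the same examination and
  then conditioned on. Their estimation error propagates into the
  count model as apparent overdispersion and is not reflected in the
  reported confidence intervals, which cover counting noise only.
* **Background handling.** The pre-injection background is estimated by
  its mean and subtracted; the Poisson variance of the background
  itself remains in the data and inflates dispersion estimates for
  low-count late samples.
* **One-dimensional smooths.** All smooths are functions of time only;
  there is no covariate modelling beyond the ABSS bias indicator.
* **Kernel assumed known.** The dispersion time constant `kappa` is a
  protocol constant, not estimated.
* **AIC comparisons are in-sample.** The model-evolution experiment
  ranks models by AIC on the fitted examinations; with small suites
  the ranking of closely matched variants can be sensitive to
  individual examinations.
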