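# Methods

## Model

The median-effect equation (MEE) relates dose `x` to fraction affected
`f_a` through two drug-specific parameters:

    f_a / f_u = (x / D)^m,   f_u = 1 - f_a
    <=>  f_a(x) = 1 / (1 + (D/x)^m) = logistic(m (ln x - ln D)).

`D` (dose units) is the median-effect dose; `m` (dimensionless) the
sigmoidality (1 hyperbolic, >1 sigmoidal, <1 flat sigmoidal). The model
assumes a monotone effect saturating at 0 and 1; it does not cover
partial-efficacy drugs (plateau below 1), biphasic responses, or effects
measured on scales other than a fraction of the population.

All logarithms are natural. The linearization `y' = m x' + b` with
`y' = ln(f_a/f_u)`, `x' = ln x`, `b = -m ln D` is base-independent in
`(m, D)`; only `b` changes with the base.

Evaluation uses the logistic form with `scipy.special.expit`, which is
stable at extreme doses where the ratio form would overflow.

## Estimators

**Linearized ("standard") fit** — unweighted OLS of `y'` on `x'` over
the observations with `0 < f_a < 1` (others have no finite `y'` and are
dropped; the count is reported as `n_dropped`). `m` is the slope,
`D = exp(-b/m)`. Slope/intercept variances and covariance come from the
closed-form normal equations; `Var(D)` by the delta method on
`D(m, b)`. The Pearson `r` of the regression is reported because it is
the conventional (and misleading — see below) goodness-of-fit summary
for this method. A non-positive slope raises a degenerate-fit error
since the MEE requires `m > 0`.

**Nonlinear fit** — minimizes `sum_i (f_a,i - f_a(x_i; m, D))^2` with
every observation equally weighted, including `f_a <= 0` or `>= 1`
(noisy assays produce them and they carry real information about the
curve's tails). Positivity of `(m, D)` is enforced by optimizing
`(ln m, ln D)`, which also makes optimizer steps scale-free; the solver
is Levenberg-Marquardt (`scipy.optimize.least_squares`, analytic
Jacobian, relative tolerances 1e-10 — the problem is two-parameter and
cheap, so tight tolerances cost nothing). The starting point is the
linearized fit when feasible, else `(m, D) = (1, dose nearest
half-effect)`; on non-convergence the fit restarts deterministically
from `(1, median dose)` and `(2, geometric-mean dose)` before raising.
The `(m, D)` covariance is `(J^T J)^{-1} s^2` at the optimum, mapped
from log space by the delta method; a zero-residual fit reports a zero
covariance with a `perfect_fit` diagnostic instead of NaNs.

Why the linearized fit misbehaves: with constant noise `sigma` on
`f_a`, first-order propagation gives `sd(y') = sigma / (f_a f_u)` —
minimal at `f_a = 0.5` and divergent toward either boundary
(`linearization_noise_amplification`). Unweighted OLS on `y'` therefore
over-weights near-boundary points. On steep curves (m ≈ 2 with the
default design) this drags the fitted `m` well below truth even while
the regression's `r` stays above 0.96, giving a false impression of
quality. The direct fit has uniform weights on the scale the noise
actually lives on.

## Combination index

For a fixed-ratio (R_A:R_B) mixture whose dose axis is the **total**
dose, substituting the MEE inversion `x = D (f_a/f_u)^(1/m)` for the
three fitted curves into `CI = x_A^C/x_A^0 + x_B^C/x_B^0` gives

    CI(f_a) = D_AB/(R_A+R_B) (f_a/f_u)^(1/m_AB)
              [ R_A/D_A (f_u/f_a)^(1/m_A) + R_B/D_B (f_u/f_a)^(1/m_B) ].

The total-dose convention is native (it is what the `D_AB/(R_A+R_B)`
factor assumes); readers can convert "per ratio unit" dosing on load.
At `f_a = 0.5` every power term equals 1 and CI reduces to
`(D_AB/(R_A+R_B)) (R_A/D_A + R_B/D_B)` — independent of the `m`'s.

Verdicts classify CI(0.5): < 0.8 synergistic, > 1.2 antagonistic,
in-between additive. The boundary values 0.8 and 1.2 themselves are
classed additive: the choice has measure zero in practice and a closed
middle interval keeps the partition total. Classification uses the point
estimate, not the interval, so verdict *rates* over repeated experiments
are directly interpretable as error rates under an additive truth.

**Confidence bands** are parametric bootstrap: each fit's `(m, D)` is
resampled from its asymptotic bivariate normal in `(ln m, ln D)`
coordinates (log-space sampling keeps draws positive and better matches
the skew of a positive parameter), CI is re-evaluated per draw (default
4000), and pointwise percentile bounds are taken. Seeded and
reproducible. The delta-method standard error of CI(0.5)
(`ci_standard_error`, central differences, block-diagonal covariance
across the three independent fits) is what the Monte-Carlo study reports
as each experiment's "reported sigma"; the two uncertainty routes agree
to first order but the bootstrap is preferred for bands because CI is a
nonlinear positive functional.

## Monte-Carlo validation

`generate_dataset` emulates one plate assay: 9 doses geometrically
spaced around the generating `D` (4 each side, factor 2 — the default
`DoseDesign`), true MEE values plus i.i.d. Gaussian noise on `f_a` with
sd 0.05, **not clipped** to [0, 1]. These defaults are the study
conditions throughout; generating parameters are `D = 10` (arbitrary
units) and `m` in {0.5, 1, 2}. What the generator does *not* emulate:
dose-dependent (heteroscedastic) or correlated noise, plate edge
effects, normalization artifacts, or model misspecification — so
passing studies demonstrate estimator properties under a correct model,
not robustness to assay pathology.

Two studies, both bit-reproducible from `(config, seed)` with a single
`numpy` generator streaming draws in a fixed order (dose-major within a
dataset, dataset-major within a block):

* **Parameter recovery** (`run_parameter_study`): fit each simulated
  dataset with each method; summarize the estimate distributions and the
  mean reported standard errors. At 10000 replicates the nonlinear means
  center on truth (within 0.05 in `m`, 0.2 in `D`), while the linearized
  `m` is visibly biased low for `m = 2`.
* **Additive-truth combinations** (`run_additive_ci_study`): blocks of
  three datasets from the same curve play drug A, drug B and their 1:1
  combination, so true CI = 1 and every non-additive verdict is an
  error. Per block, CI(0.5), its delta-method sigma, and the verdict are
  recorded; `table3_report` tabulates verdict percentages per
  (generating m, method). At `m = 2`, the linearized method calls more
  than a third of truly additive blocks synergistic or antagonistic;
  the direct fit reduces that to under 3%.

Error draws are independent across doses and across the three datasets
of a block — the natural reading of per-point measurement noise. Fit
failures (possible in principle for the linearized method when fewer
than two points stay inside (0, 1), vanishingly rare at sd 0.05) exclude
the block from percentages and are counted separately, so reported
fractions always partition the classified blocks.

Default replicate count is 10000 — verdict percentages then carry
binomial standard errors of at most 0.5 points, sharp enough for every
comparison made here — with larger counts available via
`SimulationConfig`; the studies and the acceptance checks in
`tests/test_acceptance.py` run at this size.

## Packaged examples

`table1.csv` / `table2.csv` are two synthetic worked examples: an
additive pair (true CI = 1, generating m = 2, D = 10 for all three
curves) and a synergistic pair (true CI = 0.6). Both tabulate the
fraction *unaffected* — the plotting convention for such tables — and
are read with `fa_or_fu="fu"`. They are fixed realizations with noise
sd 0.05, so fitted values sit near, not on, the generating parameters;
the nonlinear analysis returns CI(0.5) = 0.988 (additive) and 0.614
(synergistic) while the linearized analysis returns 0.577 (false
positive) and 1.024 (false negative).

## Known limitations

* Two drugs only; fixed-ratio designs only. No dose-reduction index or
  isobolograms.
* The unweighted nonlinear objective is the method's definition, not an
  option: no robust losses or heteroscedastic weighting are offered.
* Asymptotic (Gauss-Markov) covariances from a 9-point fit are
  approximate; the bootstrap bands inherit that approximation.
* The nonlinear `m` estimate carries a small finite-sample upward bias
  (~2% at m = 2 with the default design), visible in the recovery study
  and well inside its spread.
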