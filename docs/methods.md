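# Methods

## Model

Concentration–response data are modeled with the four-parameter logistic in
log10-concentration space:

    R(C) = INF + (ZERO − INF) / (1 + 10^(h·(log10 C − log10 AC50)))

with `ZERO` the response asymptote at zero concentration, `INF` at infinite
concentration (both % of DMSO control), `AC50` the midpoint and `h` the Hill
slope. Internally concentrations are μM; reported `LAC50` is log10 molar
(`AC50_μM = 10^(LAC50+6)`), matching the deposited screen dialect.

Effectiveness is the asymptote span `EFF = ZERO − INF`, and the combined score
is `S = log10(EFF / AC50_μM)`. `S`'s absolute magnitude depends on the units
of response and concentration, but the pairwise difference
`ΔS = S_ref − S_test` is unitless: joint rescaling shifts both `S` values by
the same constant. ΔS < 0 calls the test line sensitive, ΔS > 0 resistant;
ΔS = 0 or an undefined side is indeterminate, with the reason retained.
`EFF ≤ 0` (flat or rising curve) makes `S` undefined rather than producing
−∞/complex arithmetic; an optional `eff_floor` can impute a minimal EFF for
no-response reference records so such pairs stay reportable, and is off by
default.

Potency-only and AUC-only analogues are computed alongside:
`ΔAC50 = log10(AC50_ref/AC50_test)`, `ΔpAC50 = −ΔAC50`, and
`ΔpAUC = −log10(AUC_ref/AUC_test)`. On all three "Δp" endpoints more-negative
means the test line is more affected. When `EFF_ref = EFF_test`, ΔS reduces
exactly to `−ΔAC50 = +ΔpAC50`.

## Aggregation and prioritization

Per compound, the ΔS mean is the simple arithmetic mean over test lines with a
defined ΔS; dispersion is tracked as the sample variance (ddof = 1) and as the
variance of the mean (sample variance / n). Both are emitted because summary
tables in this field print sometimes one, sometimes the other.

A compound is prioritized when all of:

* **Fit quality.** R² ≥ `r2_threshold` (default 0.8) in every test line and in
  the reference. The default `r2_mode = per_line` applies the threshold to
  each line; `r2_mode = mean` instead thresholds the mean test-line R² — the
  looser reading of "average R² of at least 0.8". A reference record with no
  concentration–response (or a stimulatory profile) is exempt from its R²
  requirement. A line with no record or no R² at all excludes the compound
  (`excluded:missing_fit`) rather than silently shrinking n.
* **Effect size.** |ΔS mean| > `ds_mean_threshold` (default 0.5, ≈ 3-fold
  arithmetic). The sign sets the verdict direction.
* **Non-inferiority.** |ΔS mean| − √(variance of the mean) ≥ `variance_floor`
  (default 0.3, ≈ 2-fold). This operationalizes "the lower boundary of the
  variance-discounted effect must clear a margin": the point estimate minus
  one standard error of the mean must remain meaningfully non-null. With
  fewer than two defined lines the bound is undefined and the compound cannot
  be prioritized.

Every predicate and its inputs are recorded in an audit dict on the summary.
The filters are monotone: shrinking the variance of the mean or growing
|ΔS mean| never demotes a passing compound.

`ΔΔS = ΔS mean(tumor group) − ΔS mean(control group)` supports multi-control
designs; both group means must share the designated reference (enforced), and
group means are unweighted means of member summaries.

Endpoint comparison uses squared Pearson correlations (listwise deletion per
cell, n reported, undefined on zero variance) and ascending average-rank
tables per endpoint mean — rank 1 is the most sensitive compound under each
endpoint — with pairwise Spearman ρ as the concordance measure.

## Fitting: numerical choices

* **Bounds.** Asymptotes in [−50, 250] % control (screens show low-dose
  responses above 100 %), |h| ≤ 10, and log10 AC50 within the tested
  concentration range ± 3 decades to prevent unbounded extrapolation.
* **Multi-start.** Starts seed `ZERO`/`INF` at the response extremes, the
  midpoint at the concentration whose response is nearest half-range, and
  h ∈ {±0.5, ±1, ±2}. Lowest residual sum of squares wins; near-ties break
  toward the smaller |h|.
* **Canonical labeling.** The 4PL is invariant under swapping the asymptotes
  and negating h. Fits are canonicalized so `asym_zero` is the
  zero-concentration limit (h ≥ 0 after canonicalization); without this the
  optimizer's arbitrary labeling flips EFF's sign. Rising (stimulatory)
  curves therefore appear as `INF > ZERO` and are flagged, not refit with a
  different model; hormesis (rise then fall) is outside the model family and
  will surface as a poor R².
* **Quality.** R² is computed on the raw points against the mean-response
  null and may be negative. A series needs ≥ 5 distinct concentrations for
  the 4-parameter fit; flat series are returned as
  "no concentration-response" rather than fitted. AUC is the trapezoidal
  integral of the fitted curve over log10 concentration (default grid 1001
  points, converging to the analytic integral); a raw-trapezoid AUC over the
  observed points is available as a fallback for dialects whose deposited
  AUC was point-based.

## Synthetic screens

The generator emulates the deposited data shape: 1 reference + 4 test lines,
an 11-point log-spaced concentration grid over 10⁻³–10² μM, responses in %
control with additive homoscedastic Gaussian noise (default σ = 5 % control).
Truth priors: `ZERO ~ Normal(100, 5)`, `INF ~ Uniform(0, 60)`, log10 AC50
uniform over the grid interior (1.5 decades inside each edge, so midpoints
are identifiable), `h ~ Uniform(0.5, 3)`. Compounds draw an effect class:
null (30 %), sensitive (25 %, test AC50 shifted one decade down at equal EFF,
true ΔS = −1 exactly), resistant (25 %, one decade up, ΔS = +1),
partial responder (10 %, equal AC50 but test EFF in 20–50 % control — the
case ΔpAC50 is blind to), stimulatory (10 %, test `ZERO` in 105–130 %
control). Class proportions straddle the prioritization thresholds so the
filter logic is exercised on both sides. The prefitted-dialect output carries
the noiseless true parameters so scoring can be tested independently of
fitting; the truth sidecar carries per-record EFF/S and per-pair ΔS and is
never mixed into the main tables. A seed fully determines every output.

What the generator does **not** emulate: plate/edge effects, DMSO
normalization artifacts, heteroscedastic or correlated noise, compound
classes with mixed per-line effects, or missing wells. Passing tests
therefore demonstrate the correctness of the scoring and filtering machinery
and the fitter's statistical behavior under idealized noise — not robustness
to real screening artifacts.

Problem sizes used by the checked-in verification runs: 200 curves
(40 compounds × 5 lines) for parameter-recovery statistics and a
50-compound × 5-line screen for the end-to-end recall measurement.

## Known limitations

* **Shallow-curve identifiability.** For shallow slopes (h ≈ 0.5), a high
  `INF` and screen-level noise, the bounded 4PL likelihood can prefer a
  near-linear boundary solution (asymptote pinned at 250) whose residual sum
  of squares genuinely beats the generating parameters — the data simply do
  not constrain the asymptotes. Such fits can pass the R² filter while badly
  inflating EFF and extrapolating AC50.
* **Reference-side error is systematic.** Every ΔS for a compound shares the
  same reference fit, so a reference-line fitting error shifts the ΔS mean
  coherently across test lines while leaving the cross-line variance small.
  The non-inferiority filter, which only sees cross-line spread, cannot
  screen this out; occasional false-positive prioritizations of null
  compounds (observed in synthetic screens) are the result. Replicated
  reference measurements or multi-control ΔΔS designs are the remedy.
* **No multiple-testing correction** is applied to prioritization, by
  design — the procedure is a screening filter, not an inference.
* The exact header spellings and AUC normalization of externally deposited
  files vary; `column_map` and the raw-trapezoid AUC fallback exist to
  absorb this, and mixed-unit files are out of scope.
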