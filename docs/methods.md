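# Methods

## Mechanical model

A standing maize plant flexed at height *h* is modelled as a tip-loaded
cantilever with a rigid boundary at the base. The device reports
rotation in degrees; deflection at the load point is δ = h·sin θ with
θ = deg·π/180. Full machine-precision π is used everywhere; truncating
π to five digits (as printed in some field protocols) would change
slopes by less than 3×10⁻⁵ relative and is treated as a reporting
artifact, not a modelling choice.

Within the ≤ 15° protocol range the force response is taken as linear
elastic, F = k·δ, with a single stiffness *k* (N/m) per test. Real
traces show loading/unloading asymmetry; the generator captures this
with one multiplier η ∈ (0, 1] on the unloading legs (F = η·k·δ). No
constitutive model of the hysteresis is attempted — the single
multiplier is the simplest form that makes the three slope-extraction
methods genuinely different, which is all the validation needs.

Brace-root anchorage enters multiplicatively: whorl *j* (counting from
the soil) carries a factor f_j ∈ (0, 1], and excising the top
soil-entering whorl multiplies the plant's true slope by that whorl's
factor. This makes the analysis-side adjacent-label ratios *identical*
to the generator parameters and the overall contribution ratio equal to
∏f_j, so parameter recovery is the natural end-to-end check.

## Cycle parsing

A loading cycle starts at the first sample of a maximal run of
**strictly** increasing deflection of length ≥ `min_run` (default 10)
and extends to the end of that run; runs spanning < `min_span_m`
(default 0.02 m) are discarded. Two conventions here were genuinely
open and are our choices: strict rather than weak monotonicity (noise
makes exact ties rare, and strictness is a crisp, testable rule), and
extending each cycle to the end of its maximal run (the start criterion
alone does not define an end). Equal consecutive deflections therefore
break a run.

## Slope extraction

All line fits include an intercept: field load cells carry pre-contact
offsets, and only the slope is interpreted. The three methods:

* **full** — OLS over every sample. Default, because it needs no
  segmentation and is therefore immune to wind-corrupted parsing.
* **loading** — OLS pooled over accepted cycles only.
* **ransac** — per-cycle RANSAC (scikit-learn's `RANSACRegressor`,
  `min_samples = 2`, `max_trials = 200`, explicit seed). The residual
  threshold is 1.5 × the median absolute residual of a preliminary
  full-trace OLS, so it adapts to each trace's noise floor; on an
  exactly noise-free trace the threshold degenerates to a tiny positive
  tolerance so that all points are inliers. "Longest continuous data"
  is operationalized as the longest run of *consecutive-index* inliers
  within a cycle — the reading that penalizes mid-cycle disturbances —
  with ties broken to the earliest cycle.

When no cycle passes the filters, loading/ransac raise a no-cycle error
and the pipeline (with `fallback_to_full`, the default) substitutes the
full-trace fit, flagging the row. Failures and fallbacks are always
flagged, never silently dropped.

## Contribution statistics

Ratio, difference and per-whorl ratios follow the definitions in the
README. Single-label series (no whorls in the soil) return ratio 1,
difference 0 and no whorl ratios, by convention. The telescoping
identity ∏(whorl ratios) = ratio holds at machine precision and is
enforced by property tests.

The beam-length correction divides the observed ratio by ((h−a)/h)³.
The direction of such a correction is not universal; the anchor we rely
on is internal: under the pure-geometry null (anchorage unchanged, beam
lengthened from h−a to h, slope ∝ 1/L³ at constant EI) the corrected
ratio is exactly 1, and a = 0 is the identity. The opposite reading
(multiplication) is exposed via `direction="multiply"` for comparison
but is not the default. Plants without a measured attachment height
skip the correction rather than guessing one.

## Statistics layer

* ANOVA/Tukey use scipy (`f_oneway`, `tukey_hsd`); the two-way model is
  additive (main effects only) via statsmodels, since the designs this
  package serves report main effects.
* Repeatability is agreement ICC from one-way ANOVA variance
  components, with the unbalanced-design effective group size n₀ and
  the negative between-group component truncated at 0. SE and the 95%
  interval come from a parametric bootstrap (Gaussian components
  resampled on the observed design, default 1,000 draws); the p-value
  against R = 0 is a label-permutation test (default 1,000 shuffles).
  A permutation test was preferred to a likelihood-ratio test because
  it is assumption-light and exactly reproducible under a seed. The
  ANOVA-ICC estimator is slightly downward biased at 23 groups (the
  calibration study recovers ≈ 0.86 when the truth is 0.876, within the
  ±0.05 band we validate).
* The Tukey ladder of powers searches λ ∈ [−2, 2] in steps of 0.025
  (x^λ for λ>0, log x at 0, −x^λ for λ<0, all order-preserving),
  maximizing Shapiro–Wilk W. Since λ = 1 is in the grid, the selected
  transform never has lower W than the raw data. The normality gate
  defaults to transforming when normality is *rejected* (p < α); the
  literal opposite gate (`normalize_when="p_ge"`) is selectable for
  reproducing workflows written that way.
* The two-predictor regression is plain OLS with t-test p-values.

## Synthetic generator: what it emulates and what it does not

Emulated: the triangle-wave rotation protocol (3 cycles to 15°, 50
samples per leg ⇒ 294 samples per trace), linear-elastic response with
per-whorl factors, unloading hysteresis, iid Gaussian force noise, wind
bursts as AR(1) (Ornstein–Uhlenbeck-like, coefficient 0.9) disturbances
added to the *recorded rotation* over a contiguous window — rotation is
the channel whose corruption breaks monotone-run parsing, which is the
observed field failure mode — plant-level lognormal stiffness
variation, and repeat-test designs with a controlled intraclass
variance share.

Not emulated: soil constitutive behaviour, root depth, distributed root
mechanics, device compliance, operator re-positioning drift beyond a
white residual, temperature/turgor dynamics within a test. Passing the
recovery tests therefore shows the *pipeline arithmetic* is correct and
well calibrated under the stated noise model; it does not certify the
cantilever model against real plants.

Default parameters (all configurable):

| parameter | default | why |
|---|---|---|
| base slope k_A | lognormal, median 40 N/m, σ_log 0.25 | mid-range of field FD slopes for maize at reproductive stages |
| whorl factors | (0.65, 0.85, 0.95) | soil-closest whorl contributes most, higher whorls successively less |
| force noise | 0.5 N | assumption; no published noise floor for these devices |
| hysteresis η | 0.8 | visible loading/unloading split without pathological fits |
| load height | 0.64 m | protocol value (0.60 m selectable) |
| attachment height a | uniform 0.015–0.032 m | measured field range |
| repeat design | 23 plants × 3 tests, share 0.876 | the repeatability design this package validates against |
| line means | n = 26, predictor r = 0.8, sd 5.6 d / 21.6 cm, noise 2.0 | chosen by closed form so the expected fit lands near R² ≈ 0.40 with a strong flowering-time and marginal height effect — the regime the regression contract targets |

## Problem sizes used in validation

The acceptance script and the end-to-end tests use: 7 slopes spanning
10–100 N/m for exact recovery; 1,000 random series for the telescoping
identity; 200 three-whorl plants for factor recovery (observed MAE
≈ 0.02 against a 0.05 bound); 200 replicate 23 × 3 repeat designs for
repeatability calibration; 2,000 null datasets (3 × 20) for type-I
calibration; 100 plants for the cross-method correlation check. These
sizes keep each quantity's Monte-Carlo error well below the band it is
checked against.

## Known limitations

* The cycle parser's strict-increase rule can split one physical
  loading leg into several runs under heavy noise; the span filter then
  discards fragments, which is intended but means very noisy traces
  fall back to the full fit rather than yielding a loading-only slope.
* Repeatability assumes Gaussian components; heavy-tailed technical
  variation would call for a rank-based or mixed-model alternative.
* The beam-length correction inherits the 1/L³ cantilever idealization;
  guy-wire-like tension effects of brace roots are deliberately outside
  the correction's null.
* `compare_methods` drops traces where any method fails (listwise), so
  its correlation matrix describes the mutually extractable subset.
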