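# Methods

## The measurement model

A fluorescence-mode laparoscope renders ICG signal as a green overlay on an
8-bit RGB frame. `icgquant` treats the frame as three equal-shape channel
matrices of integers in [0, 255] and assumes that perfusion signal lives in
the green channel while specular reflections are achromatic. The pixel
filter retains a pixel iff `G > R` and `G > B`, with strict inequalities:
ties are discarded, so every neutral gray — including pure white
(255, 255, 255) reflections and black — fails. "Predominant" admits several
readings; strict dominance is the minimal one that makes all achromatic
pixels non-green, and it is what the filter implements. The filter is
applied before any statistic; no smoothing or other pre-filtering is done.

ROIs are axis-aligned rectangles in 0-based, row-major, half-open
coordinates. Per-ROI statistics (mean, median, quartiles by linear
interpolation between order statistics, min/max, sample SD with the n−1
denominator, 256-bin histogram) are computed over retained pixels only. An
ROI whose retained fraction falls below a configurable minimum (default
50%) is flagged `low_retention`; an ROI with no retained pixels is an error
at the single-ROI level and is excluded (with a warning) from segment
pooling. The segment-level mean pools the union of retained pixels across
all ROIs with equal pixel weight — deliberately *not* a mean of ROI means,
so a half-masked ROI contributes half the weight.

Automatic ROI placement mimics the manual sampling protocol: rejection
sampling of non-overlapping squares (default ten 10×10 squares) that
contain no pixel with `G ≥ 250` (near-saturated vessel highlights distort
the intensity scale near 255) and keep the retained fraction above the
minimum. Placement is deterministic given the seed.

## Perfusion metrics

For one intestinal segment:

* `MISPreI` — the mean over subjects of the pre-ischemia readings.
* `MISPostI` — the flat mean over **all** available post-ischemia readings,
  pooled across subjects and times. Subjects with missing late time points
  therefore contribute fewer readings; this unequal weighting is the only
  one consistent with the built-in study's printed summary values
  (pre mean 146.9743 with n = 7 and pooled post mean 99.0839 with n = 31
  for the left colon), and it is verified by a regression test.
* `AMISD = MISPreI − MISPostI`, may be negative when a segment brightens.
* `RMISD = (1 − MISPostI/MISPreI) × 100`, undefined when `MISPreI = 0`.

Classification uses a closed threshold: `RMISD ≥ threshold` calls the
segment ischemic. The default threshold of 32.6% is an experimental
estimate from a pig model of complete devascularisation and is exposed as a
parameter, not treated as a clinical constant. Note the built-in study
itself yields RMISD = 32.5842, which sits just below its own rounded 32.6
cutoff; the classifier reports `False` there by design of the closed rule.

Missing observations (animal losses) are skipped, never imputed. The
built-in fixture preserves each printed phase table verbatim, including the
fact that the pre and post phases list different animal rosters
(1,2,3,5–8 pre; 1,2,4–8 post); no join across phases is forced. One
published summary value — the pooled right-colon post-period "mean 140,
95% CI 134.2–145.7" — is not reproducible from the per-animal values
(which pool to 141.25, CI 135.0–147.5) and is documented here rather than
matched.

## Statistics

Group comparisons use the pooled (equal-variance) unpaired two-sample
t-test with `df = n_a + n_b − 2`; only this form reproduces the study's
printed confidence intervals for the mean difference (e.g. −31.61512 to
21.53512 for the right colon, pre vs 15 min). Welch and paired variants
were rejected on that evidence. Descriptive confidence intervals are
`mean ± t(n−1, 1−α/2)·sd/√n`. Stability over time is screened by one-way
unbalanced ANOVA; for the control segment the pre group is included with
the five post-time groups (the whole-experiment stability question), while
the ischemic segment is screened over the post period only, since its pre
level is expected to differ. Normality screening is a one-sample
Kolmogorov–Smirnov test against a normal with the sample's estimated mean
and SD; the classical p-value is conservative when parameters are estimated
(the Lilliefors problem), so a Lilliefors-corrected variant is available
behind a flag. No multiple-testing correction is applied across the
per-time comparisons, mirroring the original analysis; a log note is
emitted when more than two comparisons are reported together. Reports
round p-values to 3 dp and table values to 4 dp; full precision is kept in
the JSON outputs.

## Synthetic data

`generate_synthetic_image` emulates what matters to the filter and nothing
more: a uniform tissue field `base_green` with i.i.d. Gaussian per-pixel
noise (rounded and clipped to [0, 255]), a low red/blue background,
exactly `⌊reflection_fraction·H·W⌋` pure-white pixels, and 3-column-wide
vertical vessel streaks forced to G = 255. It does not model optics,
vignetting, JPEG compression, spatial perfusion gradients or motion, so
passing recovery tests demonstrate correctness of the filtering/pooling
arithmetic, not robustness to real acquisition artefacts. Clipping bias is
negligible for interior levels: the truncated-normal mean bias is < 0.01
intensity units once the nearer clip boundary is ≥ 3.5 SD away, and ≈ 0.044
at a 3-SD boundary (base 30, SD 10) — the tests assert these analytic
bounds.

`simulate_study` draws one baseline per subject,
`pre_i ~ N(mu_pre, sigma_between)`, applies i.i.d. measurement noise
`N(0, sigma_time)` to every observation, multiplies the ischemic segment's
post-ischemia level by `(1 − drop_fraction)` (a multiplicative drop,
matching the scale-relative RMISD), and drops the two late time points per
subject with probability `dropout_prob`. Defaults mirror the experimental
conditions: 8 subjects, `mu_pre = 147`, `sigma_between = 13` (the left-colon
pre-phase SD ≈ 13.3), `sigma_time = 5` (the within-subject stability of the
post series), `drop_fraction = 0.326`, `dropout_prob = 0.25` (two of seven
post-phase animals lost late readings). Pre observations of both segments
receive measurement noise around the shared baseline — a noiseless shared
pre value would make the between-segment pre comparison degenerate. A drop
exactly at the classification threshold puts RMISD on the decision
boundary, so the end-to-end CLI check of the binary call uses a clearly
supra-threshold drop (0.40), while recovery of the 0.326 drop itself is
asserted on the mean RMISD over 500 seeds (within ±1.5 percentage points).

## Numerical and design choices

* Quartile convention: linear interpolation (NumPy default), recorded in
  the summary-JSON metadata.
* Pixel exports are CSV (`row,col,green` plus a `#`-commented summary
  block) so they re-parse losslessly; spreadsheet-native formats are out of
  scope.
* Test fixtures are lossless PNG; JPEG decoding is library-dependent at the
  pixel level and the algorithm is format-agnostic.
* Alpha channels are dropped with a logged warning; bit depths other than
  8 per channel are rejected.
* All randomness (ROI placement, both generators) flows from a single
  user-supplied seed through `numpy.random.default_rng`.
* The built-in study fixture self-verifies on first use: the per-time group
  means recomputed from the transcribed per-animal values must match the
  published summary means to 4 dp, or construction fails loudly.

## Problem sizes in the test suite

Monte-Carlo checks use 100 repetitions × n = 5000 for the KS calibration
and power checks, 200–500 seeds of the study simulator for recovery
checks, and 64×64 to 80×80 synthetic frames for imaging recovery; the
end-to-end image pipeline test renders one 64×64 frame per observation for
a 3-subject study. These sizes keep the full suite around ten seconds
while leaving Monte-Carlo standard errors well inside the asserted
tolerances.

## Known limitations

* Works only on RGB renderings where perfusion maps to green dominance;
  grey-scale infrared exports are out of scope.
* Still images only; no video, kinetics (time-to-peak, inflow slope) or
  per-pixel ischemia maps.
* The 32.6% threshold is a single-model estimate with no uncertainty
  attached; treat the binary call as a screening aid.
* The statistics assume independent observations within each group; the
  repeated measures over time are not modelled (no mixed effects), matching
  the original analysis.
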