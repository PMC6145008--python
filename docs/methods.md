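# Methods

This note records the models, conventions, and numerical choices behind
`hrvc`, in the spirit of a software methods appendix: what is computed,
which decisions were genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Signal ingestion

**Filtering.** Waveforms are denoised by a direct FFT transform–mask–
inverse band filter with no detrending: the spectrum is multiplied by a
binary mask over [low, high] Hz and inverted; the mean survives only if
the passband includes 0 Hz.  Default passbands are 0.5–40 Hz for ECG and
0.5–8 Hz for PPG — conventional monitoring bandwidths, configurable,
since the exact cutoffs used with clinical recordings of this kind are
typically not reported.  The filter is linear and length-preserving.

**Beat detection.** A derivative-energy detector in the Pan–Tompkins
style: band-limit (5–30 Hz), differentiate, square, integrate over
150 ms, threshold at a fraction of the peak energy, then refine each
candidate to the raw-signal extremum and a parabolic sub-sample vertex.
A 250 ms refractory period suppresses double detections.  PPG pulse
peaks are detected directly on the low-passed pulse wave; when both
channels are available, ECG is authoritative and PPG serves as an
agreement check (the two recovered interval series agree within ±4 ms on
clean synthetic data).  A flatline trace returns an empty beat sequence
with an explicit warning rather than silently succeeding.

**Ectopic screening.** Clinical practice often screens ectopic beats
visually; for reproducibility the package uses a deterministic running-
median rule: an interval deviating from the median of its 11-beat window
by more than 20 % is flagged ectopic.  Actions: `flag` (default, keeps
values), `interpolate` (replace by the local median, flagged `edited`),
or `delete`.  Flagging is idempotent and the flagged fraction is always
reported.

**Segmentation.** The analysis consumes the maximal prefix of intervals
whose cumulative sum fits in the configured duration (default 600 s =
10 min, offset configurable, start-of-recording by default).  A shorter
recording raises an error naming the available duration.

## Multiscale entropy and the Complexity Index

Coarse-graining at scale τ averages non-overlapping windows of length τ
(output length ⌊N/τ⌋, trailing partial window dropped; τ = 1 is the
original series).  Sample entropy uses the Richman–Moorman conventions:

- template length m = 2, counted over the N − m start positions that
  admit both a length-m and a length-(m+1) template;
- Chebyshev (max-coordinate) distance, matches at distance ≤ r·SD;
- self-matches excluded; both probabilities share one normalization so
  constants cancel in the ratio;
- tolerance r = 0.15 as a fraction of the **scale-1** segment's sample
  standard deviation (ddof = 1), held fixed across scales — the standard
  multiscale convention.  A `per_scale_sd` option recomputes the SD per
  coarse series, because published analyses are often silent on this
  point; the convention used is recorded in every curve.

Matching pairs are counted with a k-d tree (`scipy.spatial.cKDTree`,
p = ∞), which is exactly equivalent to brute-force template counting
(asserted in the tests) and fast enough for N ≈ 10⁴.

Zero matches at either template length make SE undefined at that scale:
the value is NaN, the scale is flagged, and strict complexity-index
summation raises an error naming the scale instead of silently summing a
partial range.  A zero-variance series yields SE = 0 at every defined
scale (every template matches).

CI_s sums scales 1–5 and CI_l scales 6–10.  The frequency-band reading
of these ranges (≈0.15–0.4 Hz and ≈0.04–0.15 Hz at typical heart rates)
is documentation only; no spectral analysis is performed.  The reference
diagnostic rule `CI_l < 4.876 → UWS, ≥ → MCS` is exposed as
`classify_by_threshold`, with the boundary value belonging to the upper
bin.

**Analytic check.** For iid Gaussian data the conditional match
probability is erf(r/2σ), so with the fixed-tolerance convention the
expected curve is SE(τ) = −ln erf(0.075·√τ).  The test suite holds the
estimator to this limit within Monte-Carlo error at N = 9000, and
verifies the classic complexity ordering: 1/f noise overtakes white
noise at deep scales.

## Group statistics

The Mann-Whitney U test is exact by default up to pooled n = 30: the
null distribution of the rank sum is built by a count recursion (dynamic
program) over all C(n₁+n₂, n₁) labelings of the pooled mid-ranks, which
handles ties without approximation.  (Naive enumeration becomes
impractical around n ≈ 25; the recursion is cheap well beyond the cohort
sizes used here, so the exact path covers the 16 + 14 design.)  The
two-sided p doubles the smaller one-sided tail, capped at 1.  A
tie-corrected, continuity-corrected z is always reported alongside,
because clinical software often prints z for "exact" tests; beyond the
exact limit the normal approximation is used and flagged.

Spearman's ρ is the Pearson correlation of mid-ranks (tie-corrected),
with a t-approximation p (df = n − 2) and an exact permutation option
for n ≤ 10.  Mid-ranks matter here because behavioural totals (CRS-R)
are small integers with many ties.

## One-R classification

Each candidate attribute (CI_s, CI_l) is discretized by a greedy sweep
of the sorted values: a bucket grows until its majority class holds at
least `min_bucket` members (default 6, the conventional default for
this algorithm), then keeps absorbing consecutive examples of that same
majority class — and never splits identical values across a boundary —
before closing.  Adjacent buckets with equal majority labels are merged
and boundaries are placed at midpoints between adjacent distinct values.
The attribute with the fewest training misclassifications supplies the
rule; ties break toward the earlier feature in the configured order, and
majority ties inside a bucket break toward the lexicographically
smallest label (MCS before UWS), the same rule used by the Zero-R
baseline.

Evaluation treats MCS as the positive condition (a false positive is a
UWS patient classified as MCS) and reports the full panel: sensitivity,
specificity, FPR, FNR, per-class precision, accuracy, F1 (Dice), and
MCC, with MCC defined as 0 and flagged when a confusion-matrix marginal
is zero.  Display rounding is integer percentages and two-decimal MCC;
unrounded values are always available.

Cross-validation uses stratified folds of equal size (±1), assignment
fully determined by a mandatory seed, each record tested exactly once,
and metrics computed on the pooled (micro-averaged) confusion matrix —
matching the convention of printing a single matrix for a k-fold test.

## Synthetic cohorts

The generator is a test fixture with analytic limits, not a
physiological model.  A tachogram is

  x_i = μ + A_LF sin(2π·0.1·t_i + φ₁) + A_HF sin(2π·0.25·t_i + φ₂) + ε_i,

with μ = 800 ms, target SD 40 ms, oscillations sampled at nominal beat
times, and ε a seeded mixture of 1/f (spectrally shaped white Gaussian)
and white noise.  A single `regularity` knob g ∈ [0, 1] fixes the
deterministic share of the variance (oscillation amplitudes rescaled so
their variance is g·SD², noise carrying 1 − g); when unset, the default
amplitude fractions (0.4/0.3 of SD) are used as-is.  Intervals are
clipped to 300–2000 ms (events counted) and trimmed to the minimal
prefix covering the requested duration.

Cohorts draw a latent complexity c per subject (uniform, group centers
separated by `complexity_gap`, default 0.55; gap 0 is the exchangeable
null).  A piecewise-linear anchor map sends c to regularity
(0.975 → 0.30) — piecewise because the entropy response is steep above
g ≈ 0.9 and saturates below g ≈ 0.5, and a linear map would bunch all
cohorts at high entropy.  The pink share of the noise is 0.15 + 0.8c.
CI values are computed through the real entropy pipeline, never
short-cut.  CRS-R-like totals are round(3 + 13c + N(0, σ)) clamped to
3–16, with σ = 3.5 calibrated once so the cohort-level Spearman
ρ(CRS-R, CI_l) concentrates in the 0.5–0.8 band; these constants are
frozen.

With these defaults, UWS-like subjects land at CI_l ≈ 2.8–5.4 and
MCS-like at ≈ 6.7–9.2, straddling the reference decision threshold
(≈4.9).  What passing tests show: the estimator is exact against
brute-force counting, matches closed forms in analytic regimes, the test
statistics are correctly sized on a true null, and the classifier
recovers planted boundaries.  What they do not show: anything about real
patient data — the generator has no ectopy model beyond planted
outliers, no non-stationarity, no circadian or sedation effects, and its
group separation is a chosen study condition, not an empirical finding.

Stylized waveforms render each beat as a Mexican-hat QRS (10 ms
half-width) with small P/T bumps, or as a delayed smooth pulse wave for
PPG, evaluated at continuous beat times so that noiseless round trips
(generate → render → detect → entropy) reproduce the directly computed
complexity indices within 2 % per index.

## Problem sizes and numerical notes

- Analytic-limit and complexity-ordering checks run at N = 9000 with
  100 and 50 replicates; the null-calibration check uses 1000 cohort
  replicates; replicate seeds are drawn from a master generator.
- The exact Mann-Whitney path is the default up to pooled n = 30;
  enumeration oracles in the tests go to n = 10.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); cohort generation, fold assignment, and
  waveform noise are bit-reproducible per platform given the seed.
- Degenerate inputs are contracts, not crashes: flatline traces warn,
  short series flag undefined scales (with a warning when the deepest
  scale cannot be formed), constant inputs to correlation raise a named
  error, and single-class cohorts produce flagged degenerate models.

## Known limitations

- The beat detector targets clean, single-channel recordings; it is not
  a replacement for a clinical-grade QRS detector on artefact-heavy
  ECG.
- Sample entropy at deep scales of a 10-minute tachogram (≈75 points at
  τ = 10) is a high-variance estimate; undefined-scale flags become
  common below ~40 beats per coarse series.
- The One-R discretization follows the classic greedy algorithm;
  implementations differ in tie handling, so fitted boundaries may
  differ from other toolboxes in degenerate configurations.
- The z statistic printed alongside the exact Mann-Whitney p follows
  one common continuity/tie convention; other software may print
  slightly different z for identical data.
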