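# hrvc — heart-rate-variability complexity analysis

`hrvc` implements a complete, tested pipeline for assessing the
*complexity* of heart-rate dynamics and using it as a bedside marker of
the level of consciousness in patients with chronic disorders of
consciousness — unresponsive wakefulness syndrome (UWS) versus minimally
conscious state (MCS).  It is aimed at physiological-signal researchers
and biostatisticians who want a reproducible, scriptable version of the
analysis chain: ECG/PPG → tachogram → multiscale sample entropy →
Complexity Indices → group statistics → a One-R diagnostic rule with
cross-validation.

## The statistic

From a 10-minute interbeat-interval (RR) series *x₁…x_N* (ms), each
scale *τ* = 1…10 is coarse-grained by non-overlapping window averages,

  y_j^(τ) = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i ,  j = 1 … ⌊N/τ⌋,

and scored with sample entropy (m = 2, r = 0.15·SD of the original
segment, Chebyshev distance, self-matches excluded):

  SE(m, r, N) = −ln [ φ^{m+1}(r) / φ^m(r) ],

the negative log of the conditional probability that templates matching
for m points also match for m + 1.  The Complexity Index sums SE over
scales — CI_s over τ = 1–5 (high-frequency, vagal regime) and CI_l over
τ = 6–10 (low-frequency, sympathetic regime).  Low CI_l indicates overly
regular, oscillation-dominated heart-rate dynamics; in this population a
single-attribute One-R rule of the form *CI_l < threshold → UWS,
CI_l ≥ threshold → MCS* is a strong discriminator.

Because no patient recordings are distributable, the package ships a
first-class synthetic cohort generator (`hrvc.synthetic`) whose
tachograms mix Mayer-wave and respiratory oscillations with 1/f and
white noise, with analytic entropy limits used throughout the test
suite.

## Worked example

```python
from hrvc import CohortSpec, RunConfig, generate_cohort, run_cohort

cohort, series = generate_cohort(CohortSpec(n_mcs=16, n_uws=14, seed=1))
report = run_cohort(cohort, RunConfig(seed=1))

mw = report["statistics"]["mann_whitney_ci_l"]
print(f"median CI_l  MCS {mw['median_mcs']:.2f}  UWS {mw['median_uws']:.2f}")
print(f"Mann-Whitney U={mw['U']:.0f}  z={mw['z']:.2f}  p={mw['p']:.2e}")
print("One-R rule:", report["one_r"]["rule"])
print("10-fold CV accuracy:", report["cross_validation"]["display"]["accuracy"], "%")
```

prints

```
median CI_l  MCS 8.59  UWS 5.49
Mann-Whitney U=224  z=4.64  p=1.38e-08
One-R rule: ci_s < 8.481 -> UWS; ci_s >= 8.481 -> MCS
10-fold CV accuracy: 100 %
```

The simulated MCS group shows markedly higher long-scale complexity than
the UWS group (exact Mann-Whitney p ≈ 10⁻⁸), CRS-R behavioural totals
correlate with CI_l (Spearman ρ ≈ 0.7), and the One-R rule separates the
groups perfectly on this cohort — on synthetic data both indices
separate cleanly, so the feature tie-break picks `ci_s`; on clinical
data CI_l is the reported discriminator.

The same stages are available from the shell:

```sh
hrvc simulate --n-mcs 16 --n-uws 14 --seed 1 --out-dir cohort/
hrvc extract  --input ecg.csv --rate 500 --band 0.5 40 --segment 600 --out s01.rr
hrvc entropy  --input s01.rr --m 2 --r 0.15 --scales 10
hrvc stats    --cohort cohort/cohort.csv
hrvc classify --cohort cohort/cohort.csv --cv 10 --seed 42
```

## Layout

- `hrvc.signal_ingest` — waveform/RR IO, FFT band filtering, QRS/pulse
  detection, ectopic screening, segment extraction
- `hrvc.multiscale_entropy` — coarse-graining, sample entropy, MSE
  curves, complexity indices, the threshold rule
- `hrvc.group_stats` — exact Mann-Whitney U, Spearman correlation
- `hrvc.oner` — One-R induction, Zero-R, metrics, cross-validation
- `hrvc.synthetic` — tachogram/waveform/cohort generators
- `hrvc.pipeline`, `hrvc.cli` — orchestration and the `hrvc` command

See `docs/methods.md` for the modelling choices and their rationale.
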