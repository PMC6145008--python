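"""Synthetic tachograms, waveforms, and cohorts for pipeline testing.

No patient recordings accompany the method, so this module generates
surrogate data with the statistical structure the analysis assumes: a
10-minute interbeat-interval series is modelled as a mean heart period
plus two deterministic oscillations (a ~0.1 Hz Mayer-wave term and a
~0.25 Hz respiratory term) plus a mixture of 1/f ("pink") and white
noise.  A single ``regularity`` knob shifts variance from the broadband
noise into the oscillations: high regularity produces the
oscillation-dominated, low-complexity dynamics typical of unresponsive
patients, while 1/f-dominated, low-regularity series mimic the richer
dynamics of minimally conscious patients.  Cohorts pair each subject's
latent complexity with a CRS-R-like behavioural total through a noisy
monotone map, so rank correlations between behaviour and the complexity
indices arise the same way they do in real cohorts.

This is a test fixture with analytic limits (pure white noise recovers
the iid-Gaussian sample-entropy closed form), not a physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .multiscale_entropy import (
    EntropyParams,
    MCS_LABEL,
    UWS_LABEL,
    complexity_indices,
    mse_curve,
)
from .oner import CohortTable, SubjectRecord
from .signal_ingest import IBISeries, WaveformRecord

__all__ = [
    "SyntheticProfile",
    "CohortSpec",
    "SyntheticError",
    "pink_noise",
    "generate_ibi",
    "profile_for_complexity",
    "generate_cohort",
    "generate_planted_cohort",
    "synthesize_ecg",
    "synthesize_ppg",
]

#: Clamp range for generated CRS-R totals, mirroring the observed spread
#: of behavioural totals in cohorts of this kind.
CRS_R_RANGE = (3, 16)
#: Physiologically plausible clamp for generated intervals (ms).
IBI_CLIP = (300.0, 2000.0)


class SyntheticError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticProfile:
    """Generative parameters for one subject's tachogram.

    ``lf_amp``/``hf_amp`` are oscillation amplitudes as fractions of
    ``sd_target``.  When ``regularity`` is None the amplitudes are used
    as given (default mix: ~12.5% of variance in the oscillations); when
    set, the oscillation amplitudes are rescaled so the deterministic
    share of the total variance equals ``regularity``, and the noise
    share 1 - regularity is split between pink and white noise in the
    ratio ``pink_weight : white_weight``.
    """

    mean_ibi: float = 800.0
    sd_target: float = 40.0
    lf_amp: float = 0.4
    lf_freq: float = 0.1
    hf_amp: float = 0.3
    hf_freq: float = 0.25
    pink_weight: float = 0.5
    white_weight: float = 0.5
    regularity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_ibi <= 0:
            raise SyntheticError("mean_ibi must be > 0")
        if self.sd_target < 0:
            raise SyntheticError("sd_target must be >= 0")
        if self.pink_weight < 0 or self.white_weight < 0:
            raise SyntheticError("noise weights must be >= 0")
        if self.pink_weight + self.white_weight <= 0:
            if self.regularity is None or self.regularity < 1.0:
                raise SyntheticError("some noise weight is required unless regularity = 1")
        if self.regularity is not None and not 0.0 <= self.regularity <= 1.0:
            raise SyntheticError("regularity must lie in [0, 1]")
        if self.sd_target == 0 and (self.regularity or 0.0) < 1.0:
            raise SyntheticError("sd_target 0 requires regularity 1 (degenerate profile)")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    ``complexity_gap`` separates the latent-complexity distributions of
    the two diagnostic groups on a 0-1 scale (0 means identical
    distributions — the null); ``crs_r_noise`` is the SD of the noise
    added to the monotone latent-to-CRS-R map before rounding/clamping.
    """

    n_mcs: int = 16
    n_uws: int = 14
    complexity_gap: float = 0.55
    crs_r_noise: float = 3.5
    duration: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mcs < 1 or self.n_uws < 1:
            raise SyntheticError("group counts must be >= 1")
        if not 0.0 <= self.complexity_gap <= 1.0:
            raise SyntheticError("complexity_gap must lie in [0, 1]")


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _oscillation_amplitudes(profile: SyntheticProfile) -> tuple[float, float, float]:
    """Absolute LF/HF amplitudes (ms) and the deterministic variance share."""
    a_lf = profile.lf_amp * profile.sd_target
    a_hf = profile.hf_amp * profile.sd_target
    var_nominal = (a_lf**2 + a_hf**2) / 2.0
    if profile.regularity is None:
        share = var_nominal / profile.sd_target**2 if profile.sd_target else 0.0
        return a_lf, a_hf, share
    if var_nominal == 0:
        if profile.regularity > 0:
            raise SyntheticError("regularity > 0 requires a non-zero oscillation amplitude")
        return 0.0, 0.0, 0.0
    target_var = profile.regularity * profile.sd_target**2
    scale = np.sqrt(target_var / var_nominal)
    return a_lf * scale, a_hf * scale, profile.regularity


def generate_ibi(profile: SyntheticProfile, duration: float = 600.0) -> IBISeries:
    """Generate a tachogram covering at least ``duration`` seconds.

    Oscillations are sampled at nominal beat times (i * mean_ibi);
    residual variance is a seeded pink/white Gaussian mixture scaled so
    the total series variance is ``sd_target**2``.  Intervals are clipped
    to 300-2000 ms (clip events are counted in the metadata) and the
    series is trimmed to the minimal prefix whose cumulative sum reaches
    ``duration``.
    """
    if duration <= 0:
        raise SyntheticError("duration must be > 0")
    rng = np.random.default_rng(profile.seed)
    n = int(np.ceil(duration * 1000.0 / profile.mean_ibi * 1.25)) + 64
    t = np.arange(n) * profile.mean_ibi / 1000.0

    a_lf, a_hf, det_share = _oscillation_amplitudes(profile)
    phase_lf, phase_hf = rng.uniform(0, 2 * np.pi, size=2)
    osc = a_lf * np.sin(2 * np.pi * profile.lf_freq * t + phase_lf)
    osc += a_hf * np.sin(2 * np.pi * profile.hf_freq * t + phase_hf)

    noise_var = max(0.0, (1.0 - det_share)) * profile.sd_target**2
    wsum = profile.pink_weight + profile.white_weight
    if noise_var > 0 and wsum > 0:
        p_share = profile.pink_weight / wsum
        noise = np.sqrt(noise_var * p_share) * pink_noise(n, rng)
        noise += np.sqrt(noise_var * (1 - p_share)) * rng.standard_normal(n)
    else:
        noise = np.zeros(n)

    intervals = profile.mean_ibi + osc + noise
    clipped = int(np.sum((intervals < IBI_CLIP[0]) | (intervals > IBI_CLIP[1])))
    intervals = np.clip(intervals, *IBI_CLIP)
    cum = np.cumsum(intervals) / 1000.0
    stop = int(np.searchsorted(cum, duration, side="left")) + 1
    if stop > n:
        stop = n
    return IBISeries(
        intervals[:stop],
        metadata={"profile_seed": profile.seed, "clipped": clipped, "synthetic": True},
    )


#: Calibrated monotone map from latent complexity to the regularity knob.
#: The sample entropy of the generator responds steeply to regularity
#: above ~0.9 and saturates below ~0.5, so a piecewise-linear map is used
#: to spread CI_l roughly evenly over the clinically observed range
#: (oscillation-dominated ~2.5 up to 1/f-dominated ~9).  Frozen after a
#: one-off calibration of the generator.
_COMPLEXITY_ANCHORS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
_REGULARITY_ANCHORS = (0.975, 0.94, 0.90, 0.82, 0.62, 0.30)


def profile_for_complexity(
    c: float,
    base: SyntheticProfile | None = None,
    seed: int = 0,
) -> SyntheticProfile:
    """Map a latent complexity c in [0, 1] onto a generative profile.

    Low c gives an oscillation-dominated, nearly periodic profile
    (UWS-like); high c gives a 1/f-dominated broadband profile
    (MCS-like).  Regularity follows the calibrated anchor map above; the
    pink share of the noise variance is 0.15 + 0.8 * c.
    """
    if not 0.0 <= c <= 1.0:
        raise SyntheticError("latent complexity must lie in [0, 1]")
    base = base or SyntheticProfile()
    pink = 0.15 + 0.8 * c
    return replace(
        base,
        regularity=float(np.interp(c, _COMPLEXITY_ANCHORS, _REGULARITY_ANCHORS)),
        pink_weight=pink,
        white_weight=1.0 - pink,
        seed=seed,
    )


def _latent_complexity(rng: np.random.Generator, group: str, gap: float, size: int) -> np.ndarray:
    center = 0.5 + (gap / 2.0 if group == MCS_LABEL else -gap / 2.0)
    half_width = 0.18
    return np.clip(rng.uniform(center - half_width, center + half_width, size=size), 0.0, 1.0)


def _crs_r_total(rng: np.random.Generator, c: float, noise_sd: float) -> int:
    lo, hi = CRS_R_RANGE
    raw = lo + (hi - lo) * c + rng.normal(0.0, noise_sd)
    return int(np.clip(round(raw), lo, hi))


def generate_cohort(
    spec: CohortSpec,
    params: EntropyParams | None = None,
    return_curves: bool = False,
):
    """Generate a cohort and run it through the real entropy pipeline.

    Each subject draws a latent complexity from their group's
    distribution, receives a tachogram from :func:`generate_ibi`, and has
    CI_s / CI_l computed with :func:`hrvc.multiscale_entropy.mse_curve`
    (never short-cut).  CRS-R totals are a noisy monotone map of the
    latent complexity, clamped to 3-16.  Returns ``(CohortTable, {id:
    IBISeries})`` (plus ``{id: MSECurve}`` when ``return_curves``).
    """
    rng = np.random.default_rng(spec.seed)
    params = params or EntropyParams()
    records = []
    series = {}
    curves = {}
    groups = [(MCS_LABEL, spec.n_mcs), (UWS_LABEL, spec.n_uws)]
    for group, count in groups:
        latents = _latent_complexity(rng, group, spec.complexity_gap, count)
        for j, c in enumerate(latents):
            sid = f"{group.lower()}{j + 1:02d}"
            profile = profile_for_complexity(float(c), seed=int(rng.integers(2**31 - 1)))
            ibi = generate_ibi(profile, duration=spec.duration)
            curve = mse_curve(ibi, params)
            ci = complexity_indices(curve, strict=False)
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    diagnosis=group,
                    crs_r_total=_crs_r_total(rng, float(c), spec.crs_r_noise),
                    ci_s=ci.ci_s,
                    ci_l=ci.ci_l,
                    covariates={"latent_complexity": float(c)},
                )
            )
            series[sid] = ibi
            curves[sid] = curve
    cohort = CohortTable(tuple(records), name=f"synthetic-seed{spec.seed}")
    if return_curves:
        return cohort, series, curves
    return cohort, series


def generate_planted_cohort(
    n_mcs: int = 16,
    n_uws: int = 14,
    threshold: float = 4.9,
    margin: float = 0.5,
    seed: int = 0,
) -> CohortTable:
    """Cohort with a planted, zero-overlap CI_l decision boundary.

    UWS subjects draw CI_l uniformly below ``threshold - margin`` and MCS
    subjects above ``threshold + margin``; CI_s overlaps between groups
    so the long-scale index is the informative feature.  Used for
    parameter-recovery checks of the classifier.
    """
    if margin <= 0:
        raise SyntheticError("margin must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for j in range(n_mcs):
        records.append(
            SubjectRecord(
                subject_id=f"mcs{j + 1:02d}",
                diagnosis=MCS_LABEL,
                crs_r_total=int(rng.integers(7, 17)),
                ci_s=float(rng.uniform(3.0, 7.0)),
                ci_l=float(rng.uniform(threshold + margin, threshold + margin + 2.5)),
            )
        )
    for j in range(n_uws):
        records.append(
            SubjectRecord(
                subject_id=f"uws{j + 1:02d}",
                diagnosis=UWS_LABEL,
                crs_r_total=int(rng.integers(3, 9)),
                ci_s=float(rng.uniform(2.0, 6.0)),
                ci_l=float(rng.uniform(max(0.5, threshold - margin - 2.5), threshold - margin)),
            )
        )
    return CohortTable(tuple(records), name=f"planted-seed{seed}")


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _gaussian_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def synthesize_ecg(
    ibi: IBISeries,
    sampling_rate: float = 500.0,
    snr: float | None = None,
    seed: int = 0,
    lead_in: float = 0.5,
) -> WaveformRecord:
    """Render a tachogram as a stylized ECG trace.

    Each beat contributes a narrow symmetric QRS spike (a Mexican-hat
    pulse of unit amplitude, ~10 ms half-width) with small P and T bumps;
    optional white noise is added at amplitude 1/snr.  Beat times are
    the cumulative interval sums offset by ``lead_in`` seconds (so the
    first complex sits fully inside the record); templates are evaluated
    at the true continuous beat times, so a noiseless trace carries no
    grid-quantization jitter and sub-sample peak refinement in
    :func:`hrvc.signal_ingest.detect_beats` recovers the intervals
    almost exactly.
    """
    if sampling_rate < 100:
        raise SyntheticError(f"sampling_rate {sampling_rate} Hz too low for the QRS template")
    beat_times = lead_in + np.concatenate([[0.0], np.cumsum(ibi.intervals) / 1000.0])
    n = int(np.ceil((beat_times[-1] + 0.5) * sampling_rate))
    x = np.zeros(n)

    a = 0.010  # QRS half-width, s

    def _add(amp: float, center: float, width: float, mexican: bool) -> None:
        half = int(round(6 * width * sampling_rate))
        idx = int(round(center * sampling_rate))
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        if lo >= hi:
            return
        t_rel = np.arange(lo, hi) / sampling_rate - center
        u = t_rel / width
        bump = np.exp(-0.5 * u * u)
        x[lo:hi] += amp * ((1 - u * u) * bump if mexican else bump)

    for bt in beat_times:
        _add(1.0, bt, a, mexican=True)
        # low-amplitude P and T waves, well clear of the R peak
        _add(0.10, bt - 0.160, 0.025, mexican=False)
        _add(0.25, bt + 0.240, 0.050, mexican=False)

    if snr is not None and snr > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, 1.0 / snr, size=n)
    return WaveformRecord(x, sampling_rate, channel="ecg")


def synthesize_ppg(
    ibi: IBISeries,
    sampling_rate: float = 500.0,
    pulse_delay: float = 0.25,
    seed: int = 0,
    snr: float | None = None,
    lead_in: float = 0.5,
) -> WaveformRecord:
    """Render the same beat train as a smooth PPG-like pulse wave.

    Each beat produces a broad bump peaking ``pulse_delay`` seconds after
    the electrical beat time (pulse-arrival delay), so pulse-to-pulse
    intervals equal the interbeat intervals.
    """
    if sampling_rate < 100:
        raise SyntheticError(f"sampling_rate {sampling_rate} Hz too low")
    beat_times = lead_in + np.concatenate([[0.0], np.cumsum(ibi.intervals) / 1000.0])
    n = int(np.ceil((beat_times[-1] + pulse_delay + 0.6) * sampling_rate))
    t_axis = np.arange(n) / sampling_rate
    x = np.zeros(n)
    for bt in beat_times:
        x += _gaussian_bump(t_axis, bt + pulse_delay, 0.070)
    if snr is not None and snr > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, 1.0 / snr, size=n)
    return WaveformRecord(x, sampling_rate, channel="ppg")
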