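"""Waveform ingestion, beat detection, and tachogram construction.

This module covers everything upstream of the entropy analysis: reading
ECG/PPG traces or pre-extracted interbeat-interval (RR) files, FFT-based
band filtering without detrending, QRS / pulse-peak detection, conversion
of beat times to an interbeat-interval (IBI) series in milliseconds,
automated ectopic-beat screening, and extraction of the 10-minute
analysis segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

__all__ = [
    "WaveformRecord",
    "BeatSequence",
    "IBISeries",
    "IngestError",
    "WaveformParseError",
    "NonMonotoneTimeError",
    "InvalidBandError",
    "TooFewBeatsError",
    "NonIncreasingBeatsError",
    "WindowTooLargeError",
    "InsufficientDurationError",
    "FLAG_NORMAL",
    "FLAG_ECTOPIC",
    "FLAG_MISSING",
    "FLAG_EDITED",
    "DEFAULT_BANDS",
    "read_waveform",
    "read_ibi",
    "write_ibi",
    "fft_filter",
    "detect_beats",
    "to_ibi",
    "screen_ectopics",
    "extract_segment",
]

FLAG_NORMAL = "normal"
FLAG_ECTOPIC = "ectopic"
FLAG_MISSING = "missing"
FLAG_EDITED = "edited"

#: Default denoising passbands (Hz) per channel kind.  The source method
#: applied an FFT filter without detrending but did not publish cutoffs;
#: these are conventional monitoring-bandwidth choices and configurable.
DEFAULT_BANDS = {"ecg": (0.5, 40.0), "ppg": (0.5, 8.0)}


class IngestError(ValueError):
    """Base class for signal-ingest failures."""


class WaveformParseError(IngestError):
    """Non-numeric or malformed waveform file content."""


class NonMonotoneTimeError(IngestError):
    """Two-column input whose time column is not strictly increasing."""


class InvalidBandError(IngestError):
    """Filter passband outside (0, Nyquist) or inverted."""


class TooFewBeatsError(IngestError):
    """Fewer than two beats: no interval can be formed."""


class NonIncreasingBeatsError(IngestError):
    """Beat times are not strictly increasing."""


class WindowTooLargeError(IngestError):
    """Ectopic-screening window exceeds the series length."""


class InsufficientDurationError(IngestError):
    """Recording shorter than the requested analysis segment."""


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled single-channel trace."""

    samples: np.ndarray
    sampling_rate: float
    channel: str = "ecg"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise IngestError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise IngestError("waveform needs at least 2 samples in one channel")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Span of the record in seconds (n / fs)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class BeatSequence:
    """Detected beat (R-peak / pulse-peak) times in seconds."""

    beat_times: np.ndarray
    detector: str
    source_channel: str
    warning: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=float))
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise NonIncreasingBeatsError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.beat_times.size)


@dataclass(frozen=True)
class IBISeries:
    """The tachogram: ordered interbeat intervals (ms) with quality flags."""

    intervals: np.ndarray
    flags: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.size and not np.all(iv > 0):
            raise IngestError("all interbeat intervals must be > 0 ms")
        if self.flags is None:
            object.__setattr__(self, "flags", np.full(iv.size, FLAG_NORMAL, dtype=object))
        else:
            fl = np.asarray(self.flags, dtype=object)
            if fl.size != iv.size:
                raise IngestError("flags and intervals must have equal length")
            object.__setattr__(self, "flags", fl)

    @property
    def n(self) -> int:
        return int(self.intervals.size)

    def __len__(self) -> int:
        return self.n

    @property
    def flagged_fraction(self) -> float:
        """Fraction of intervals not flagged normal."""
        if self.n == 0:
            return 0.0
        return float(np.mean(self.flags != FLAG_NORMAL))

    @property
    def duration(self) -> float:
        """Cumulative length of the tachogram in seconds."""
        return float(self.intervals.sum() / 1000.0)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

_SEP = r"[,;\t ]+"


def _load_numeric_table(path) -> np.ndarray:
    try:
        df = pd.read_csv(path, sep=_SEP, engine="python", header=None, comment="#",
                         skipinitialspace=True)
    except OSError as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:
        raise WaveformParseError(f"cannot parse {path}: {exc}") from exc
    # tolerate a single header line of column names
    offset = 0
    if df.iloc[0].map(lambda v: pd.isna(pd.to_numeric(v, errors="coerce"))).any():
        df = df.iloc[1:]
        offset = 1
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(np.isnan(arr).any(axis=1))[0]
    if bad.size:
        raise WaveformParseError(
            f"non-numeric content in {path} at data row {bad[0] + 1 + offset}"
        )
    if arr.shape[0] == 0:
        raise WaveformParseError(f"{path} contains no data rows")
    return arr


def read_waveform(path, sampling_rate: float | None = None, channel: str = "ecg") -> WaveformRecord:
    """Read a waveform from a single-column (amplitude) or two-column
    (time s, amplitude) CSV/text file.

    A single-column file requires ``sampling_rate``; a two-column file
    infers the rate from the uniform time step and reports the first
    timestamp as ``start_time``.
    """
    arr = _load_numeric_table(path)
    if arr.shape[1] == 1:
        if sampling_rate is None or sampling_rate <= 0:
            raise IngestError("single-column input requires a sampling_rate > 0")
        return WaveformRecord(arr[:, 0], sampling_rate, channel=channel)
    t, amp = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if not np.all(dt > 0):
        raise NonMonotoneTimeError(f"time column of {path} is not strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise NonMonotoneTimeError(f"time column of {path} is not uniformly sampled")
    return WaveformRecord(amp, 1.0 / step, channel=channel, start_time=float(t[0]))


def read_ibi(path) -> IBISeries:
    """Read an RR-text file: one interval (ms) per line, optional second
    column of quality flags; CSV with a header is also accepted."""
    try:
        df = pd.read_csv(path, sep=_SEP, engine="python", header=None, comment="#",
                         skipinitialspace=True)
    except Exception as exc:
        raise WaveformParseError(f"cannot parse {path}: {exc}") from exc
    if df.iloc[0].map(lambda v: isinstance(v, str) and not _is_flag(v)).any():
        df = df.iloc[1:]
    intervals = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    if np.isnan(intervals).any():
        row = int(np.nonzero(np.isnan(intervals))[0][0]) + 1
        raise WaveformParseError(f"non-numeric interval in {path} at data row {row}")
    flags = None
    if df.shape[1] > 1:
        flags = df.iloc[:, 1].astype(str).str.strip().to_numpy(dtype=object)
    return IBISeries(intervals, flags=flags, metadata={"source": str(path)})


def _is_flag(v: str) -> bool:
    return v.strip().lower() in (FLAG_NORMAL, FLAG_ECTOPIC, FLAG_MISSING, FLAG_EDITED)


def write_ibi(ibi: IBISeries, path, with_flags: bool = True) -> None:
    """Write an RR-text file (interval ms per line, optional flag column)."""
    cols = {"interval_ms": ibi.intervals}
    if with_flags:
        cols["flag"] = ibi.flags
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def fft_filter(w: WaveformRecord, passband=(0.5, 40.0)) -> WaveformRecord:
    """Band-limit a waveform by direct transform–mask–inverse, with no
    detrending: the mean survives only if the passband includes 0 Hz.

    ``passband`` is (low, high) in Hz with 0 <= low < high < fs/2.
    """
    low, high = float(passband[0]), float(passband[1])
    nyq = w.sampling_rate / 2.0
    if not (0 <= low < high < nyq):
        raise InvalidBandError(
            f"passband [{low}, {high}] Hz invalid for Nyquist {nyq} Hz"
        )
    spec = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(w.samples.size, d=1.0 / w.sampling_rate)
    mask = (freqs >= low) & (freqs <= high)
    if low == 0.0:
        mask[0] = True
    out = np.fft.irfft(spec * mask, n=w.samples.size)
    return replace(w, samples=out)


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_beats(
    w: WaveformRecord,
    method: str = "ecg_qrs",
    refractory: float = 0.25,
    detection_band: tuple | None = None,
    threshold_fraction: float = 0.25,
) -> BeatSequence:
    """Detect beat times with a derivative-energy peak detector.

    For ECG (``ecg_qrs``) the trace is band-limited, differentiated,
    squared and integrated over a 150 ms window (Pan–Tompkins-style);
    candidate peaks above an adaptive threshold are refined to the local
    signal extremum.  For PPG (``ppg_pulse``) peaks are found directly on
    the low-passed pulse wave.  A refractory period (default 250 ms)
    suppresses double detections.  A flatline trace yields an empty
    sequence carrying an explicit warning, never a silent success.
    """
    if method not in ("ecg_qrs", "ppg_pulse"):
        raise IngestError(f"unknown detection method {method!r}")
    fs = w.sampling_rate
    x = w.samples
    if np.ptp(x) == 0 or np.std(x) < 1e-12 * (np.abs(x).max() + 1.0):
        msg = "flatline (zero-variance) trace: no beats detected"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return BeatSequence(np.array([]), detector=method, source_channel=w.channel, warning=msg)

    min_dist = max(1, int(round(refractory * fs)))
    if method == "ecg_qrs":
        band = detection_band or (5.0, min(30.0, fs / 2 * 0.9))
        filt = fft_filter(w, band).samples
        energy = _moving_average(np.gradient(filt) ** 2, int(round(0.150 * fs)))
        height = threshold_fraction * float(np.max(energy))
        cand, _ = find_peaks(energy, height=height, distance=min_dist)
        # refine each candidate to the raw-signal extremum nearby; P/T waves
        # sit farther than this window from the R peak by construction
        half = int(round(0.120 * fs))
        peaks = []
        for c in cand:
            lo, hi = max(0, c - half), min(x.size, c + half + 1)
            peaks.append(lo + int(np.argmax(x[lo:hi])))
        peaks = np.unique(peaks)
    else:
        band = detection_band or DEFAULT_BANDS["ppg"]
        filt = fft_filter(w, band).samples
        height = threshold_fraction * float(np.max(filt))
        peaks, _ = find_peaks(filt, height=height, distance=min_dist)

    # enforce the refractory period after refinement, keeping larger peaks
    ref = x if method == "ecg_qrs" else filt
    peaks = np.asarray(sorted(peaks), dtype=int)
    kept: list[int] = []
    for p in peaks:
        if kept and (p - kept[-1]) < min_dist:
            if ref[p] > ref[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    # parabolic sub-sample refinement around each integer peak
    refined = []
    for p in kept:
        delta = 0.0
        if 0 < p < ref.size - 1:
            denom = ref[p - 1] - 2 * ref[p] + ref[p + 1]
            if denom < 0:
                delta = 0.5 * (ref[p - 1] - ref[p + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
        refined.append(p + delta)
    times = w.start_time + np.asarray(refined, dtype=float) / fs
    return BeatSequence(times, detector=method, source_channel=w.channel)


def to_ibi(beats: BeatSequence) -> IBISeries:
    """Differences of consecutive beat times, in milliseconds."""
    if len(beats) < 2:
        raise TooFewBeatsError(f"need >= 2 beats to form intervals, got {len(beats)}")
    intervals = np.diff(beats.beat_times) * 1000.0
    return IBISeries(intervals, metadata={"detector": beats.detector, "channel": beats.source_channel})


# ---------------------------------------------------------------------------
# screening and segmentation
# ---------------------------------------------------------------------------

def screen_ectopics(
    ibi: IBISeries,
    deviation_fraction: float = 0.20,
    window: int = 11,
    action: str = "flag",
) -> IBISeries:
    """Flag intervals deviating from the running median of their window.

    An interval whose relative deviation from the window-local median
    exceeds ``deviation_fraction`` is marked ectopic.  ``action`` is one
    of ``flag`` (default), ``interpolate`` (replace by the local median
    and mark edited), or ``delete`` (drop the interval).  The flagged
    fraction is recorded in the output metadata.
    """
    if action not in ("flag", "interpolate", "delete"):
        raise IngestError(f"unknown action {action!r}")
    if window > ibi.n:
        raise WindowTooLargeError(f"window {window} exceeds series length {ibi.n}")
    x = ibi.intervals
    med = median_filter(x, size=window, mode="nearest")
    dev = np.abs(x - med) / med
    bad = dev > deviation_fraction

    flags = ibi.flags.copy()
    meta = dict(ibi.metadata)
    meta["ectopic_fraction"] = float(np.mean(bad))
    meta["screening"] = {
        "deviation_fraction": deviation_fraction,
        "window": window,
        "action": action,
    }
    if action == "flag":
        flags[bad & (flags == FLAG_NORMAL)] = FLAG_ECTOPIC
        return IBISeries(x, flags=flags, metadata=meta)
    if action == "interpolate":
        out = x.copy()
        out[bad] = med[bad]
        flags[bad] = FLAG_EDITED
        return IBISeries(out, flags=flags, metadata=meta)
    keep = ~bad
    return IBISeries(x[keep], flags=flags[keep], metadata=meta)


def extract_segment(ibi: IBISeries, duration: float = 600.0, offset: float = 0.0) -> IBISeries:
    """Extract the maximal run of intervals whose cumulative sum fits in
    ``duration`` seconds, starting ``offset`` seconds into the recording.

    Raises :class:`InsufficientDurationError` (naming the available
    duration) when the recording is shorter than requested.
    """
    if duration <= 0:
        raise IngestError(f"duration must be > 0 s, got {duration}")
    cum = np.cumsum(ibi.intervals) / 1000.0
    total = float(cum[-1]) if ibi.n else 0.0
    if total < offset + duration:
        raise InsufficientDurationError(
            f"recording holds {total:.1f} s but {offset + duration:.1f} s requested"
        )
    start = int(np.searchsorted(cum, offset, side="left"))
    base = cum[start - 1] if start > 0 else 0.0
    stop = int(np.searchsorted(cum - base, duration, side="right"))
    meta = dict(ibi.metadata)
    meta["segment"] = {"offset_s": offset, "duration_s": duration, "start_index": start}
    return IBISeries(ibi.intervals[start:stop], flags=ibi.flags[start:stop], metadata=meta)
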