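"""Surface-EMG conditioning and quantification.

The pipeline applied to maximum-voluntary-effort (MVE) recordings is:
powerline removal with a DFT notch (48–52 Hz), epoching per contraction
period, concatenation of the active segments, and then either
inter-muscular coherence (:mod:`neurophyskit.coherence`) or the MVErms
statistic — the maximum sliding-window rectified RMS after subtracting the
RMS of a 1 s resting signal.

Contraction periods may be supplied manually (the published workflow used
visual epoching) or detected automatically from a smoothed rectified
envelope crossing a multiple of the resting RMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io_formats import Recording, ValidationError


@dataclass
class ActiveSegments:
    """Half-open ``[start, stop)`` sample intervals of muscle activity."""

    intervals: list[tuple[int, int]]
    n_samples: int  # length of the source recording
    empty_warning: bool = False

    def __post_init__(self) -> None:
        ivs = [(int(a), int(b)) for a, b in self.intervals]
        for a, b in ivs:
            if not (0 <= a < b <= self.n_samples):
                raise ValidationError(f"interval ({a}, {b}) out of bounds")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValidationError("intervals must be sorted and non-overlapping")
        self.intervals = ivs

    @property
    def total_samples(self) -> int:
        return sum(b - a for a, b in self.intervals)


@dataclass
class MveChannelResult:
    max_windowed_rms: float
    rest_rms: float
    mve_rms: float  # baseline-subtracted, clamped at 0
    clamped: bool = False


@dataclass
class MveResult:
    """Per-muscle MVErms with the windowing actually used."""

    per_channel: dict[str, MveChannelResult]
    window_len_s: float
    step_s: float


def dft_notch(rec: Recording, stop_band: tuple[float, float] = (48.0, 52.0)) -> Recording:
    """Zero the DFT bins inside ``stop_band`` (edges inclusive).

    The forward transform of each full channel is taken, bins whose
    |frequency| lies in the stop band are zeroed (negative-frequency
    mirrors implicitly, via the real FFT), and the signal is inverted.
    Out-of-band bins are untouched, so the filter is idempotent.
    """
    lo, hi = stop_band
    nyq = rec.sample_rate / 2
    if not (0 < lo < hi < nyq):
        raise ValidationError(f"stop band {stop_band} outside (0, {nyq}) Hz")
    if rec.n_samples < 2:
        raise ValidationError("recording too short to filter")
    spec = np.fft.rfft(rec.samples, axis=0)
    freqs = np.fft.rfftfreq(rec.n_samples, d=1.0 / rec.sample_rate)
    spec[(freqs >= lo) & (freqs <= hi)] = 0.0
    out = np.fft.irfft(spec, n=rec.n_samples, axis=0)
    return Recording(rec.sample_rate, rec.channels, out, rec.units, rec.events)


def rectified_rms(signal: np.ndarray) -> float:
    """Root mean square of the full-wave rectified signal.

    Rectification is absorbed by the squaring: rms(|x|) == rms(x).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValidationError("empty signal")
    return float(np.sqrt(np.mean(signal ** 2)))


def _rest_rms(rec: Recording, channel: str, rest: Recording | None,
              rest_prefix_s: float | None) -> float:
    if rest is not None:
        return rectified_rms(rest.channel(channel) if channel in rest.channels
                             else rest.samples[:, 0])
    if rest_prefix_s is not None:
        n = int(round(rest_prefix_s * rec.sample_rate))
        if n < 1:
            raise ValidationError("rest prefix too short")
        return rectified_rms(rec.channel(channel)[:n])
    raise ValidationError("no rest reference: pass rest= or rest_prefix_s=")


def detect_contractions(
    rec: Recording,
    channel: str,
    threshold_factor: float = 3.0,
    min_duration_s: float = 1.0,
    smoothing_s: float = 0.25,
    rest: Recording | None = None,
    rest_prefix_s: float | None = None,
) -> ActiveSegments:
    """Detect contraction periods from a smoothed rectified envelope.

    An interval is active where the moving-RMS envelope (``smoothing_s``
    window) exceeds ``threshold_factor`` times the resting RMS for at
    least ``min_duration_s``.  The resting RMS comes from an explicit
    ``rest`` recording or from the first ``rest_prefix_s`` seconds of the
    recording itself.  Finding no segment is not an error: an empty result
    with ``empty_warning`` set is returned (and a warning emitted).
    """
    x = rec.channel(channel)
    base = _rest_rms(rec, channel, rest, rest_prefix_s)
    win = max(1, int(round(smoothing_s * rec.sample_rate)))
    envelope = np.sqrt(uniform_filter1d(x ** 2, size=win, mode="nearest"))
    active = envelope > threshold_factor * base
    min_len = int(round(min_duration_s * rec.sample_rate))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    intervals = [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])
                 if b - a >= min_len]
    if not intervals:
        warnings.warn(f"no contraction found on channel {channel!r}")
        return ActiveSegments([], rec.n_samples, empty_warning=True)
    return ActiveSegments(intervals, rec.n_samples)


def concatenate_segments(rec: Recording, segs: ActiveSegments) -> Recording:
    """Concatenate the active intervals, all channels aligned identically."""
    if not segs.intervals:
        raise ValidationError("no segments to concatenate (coherence undefined)")
    if segs.n_samples != rec.n_samples:
        raise ValidationError("segments refer to a different recording length")
    parts = [rec.samples[a:b] for a, b in segs.intervals]
    return Recording(rec.sample_rate, rec.channels, np.concatenate(parts, axis=0),
                     rec.units)


def mve_rms(
    trial: Recording,
    rest: Recording,
    window_len_s: float = 0.25,
    step_s: float = 0.05,
    rest_len_s: float = 1.0,
) -> MveResult:
    """MVErms per channel: max sliding-window RMS minus resting RMS.

    The resting reference is the rectified RMS of the first ``rest_len_s``
    seconds of ``rest`` (the published rule uses 1 s).  A negative
    difference clamps to 0 and is flagged.
    """
    n_rest = int(round(rest_len_s * rest.sample_rate))
    if rest.n_samples < n_rest:
        raise ValidationError(f"rest recording shorter than {rest_len_s} s")
    win = int(round(window_len_s * trial.sample_rate))
    step = max(1, int(round(step_s * trial.sample_rate)))
    if trial.n_samples < win or win < 1:
        raise ValidationError("trial shorter than one window")
    results: dict[str, MveChannelResult] = {}
    for ch in trial.channels:
        x = trial.channel(ch)
        sq = np.concatenate(([0.0], np.cumsum(x ** 2)))
        starts = np.arange(0, trial.n_samples - win + 1, step)
        window_rms = np.sqrt((sq[starts + win] - sq[starts]) / win)
        max_rms = float(window_rms.max())
        rest_ref = rectified_rms(
            (rest.channel(ch) if ch in rest.channels else rest.samples[:, 0])[:n_rest]
        )
        value = max_rms - rest_ref
        results[ch] = MveChannelResult(
            max_windowed_rms=max_rms,
            rest_rms=rest_ref,
            mve_rms=max(0.0, value),
            clamped=value < 0,
        )
    return MveResult(results, window_len_s=window_len_s, step_s=step_s)
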