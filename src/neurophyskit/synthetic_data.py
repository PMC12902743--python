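"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic given its seed and is built so the
quantity the downstream estimator recovers has a known ground truth:

* :func:`gen_emg_pair` — paired EMG whose in-band magnitude-squared
  coherence is κ² by construction.  Each channel mixes a shared
  band-limited drive ``c`` with an independent noise ``n_i`` as
  ``sqrt(κ)·c + sqrt(1−κ)·n_i``; both channels then pass through the same
  20–460 Hz Butterworth shaping filter (mirroring the acquisition
  hardware), which leaves coherence untouched, and a common 50 Hz line
  term is added last.
* :func:`gen_mve_session` — an effort trial whose windowed RMS equals a
  target envelope, plus a resting recording of known RMS.
* :func:`gen_mep_session` — a recruitment session where each trial is a
  response with probability ``sigmoid(slope·(I − θ))``; a response
  contributes ``max_amplitude`` μV plus Gaussian noise, a non-response
  only the noise (floored at 0).  The empirical response probability at
  each intensity therefore converges exactly to the sigmoid, and
  :func:`true_rmt` gives the grid intensity a perfect thresholding rule
  would return.
* :func:`gen_ssep_session` — stimulus-locked epochs of band-limited
  (0.5–500 Hz) noise with an optional fixed deflection at a set latency.
* :func:`gen_attendance` — an attendance log over the trial's phase
  schedule with configurable rates and delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .evoked import EpochSet, RecruitmentSession
from .io_formats import OUTCOME_GROUPS, Recording, ValidationError

#: Cortical stimulator-output grid: 10% steps 30–50, then 5% steps 55–100.
CORTICAL_GRID = [30.0, 40.0, 50.0] + [float(v) for v in range(55, 101, 5)]

#: Spinal grid: 10% steps over 20–160% of the target-muscle RMT.
SPINAL_GRID = [float(v) for v in range(20, 161, 10)]

#: Therapy-phase schedule: (phase, scheduled sessions).  Session counts
#: follow the trial protocol (16 FES-conditioning sessions over 6 weeks,
#: 40 TESCS-ABT sessions split 6/4/6 weeks); baseline and follow-up are
#: assessment-only sentinels.
DEFAULT_SCHEDULE = [
    ("base", 0),
    ("FES", 16),
    ("TESCS_ABT_1", 15),
    ("TESCS_ABT_2", 10),
    ("TESCS_ABT_3", 15),
    ("post_12", 0),
]


@dataclass
class CommonDriveSpec:
    """Paired-EMG generator parameters.

    ``common_fraction`` (κ) is the fraction of in-band variance shared by
    the two channels; the expected magnitude-squared coherence inside
    ``band`` is κ².
    """

    duration_s: float = 120.0
    sample_rate: float = 1000.0
    band: tuple[float, float] = (52.0, 98.0)
    common_fraction: float = 0.5
    line_amplitude: float = 0.0  # μV of the added 50 Hz component
    emg_band: tuple[float, float] = (20.0, 460.0)
    rms_uv: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.common_fraction <= 1.0:
            raise ValidationError("common_fraction must lie in [0, 1]")
        lo, hi = self.band
        if not (0.0 < lo < hi < self.sample_rate / 2):
            raise ValidationError("band must lie within (0, sample_rate/2)")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")


@dataclass
class RecruitmentSpec:
    """MEP recruitment-session generator parameters.

    ``true_threshold`` θ (% of stimulator output) is the intensity at
    which the response probability is 0.5; ``slope`` is the logistic
    steepness per %.  Five trials per intensity matches the cortical
    acquisition protocol.
    """

    true_threshold: float = 62.0
    intensity_grid: list[float] = field(default_factory=lambda: list(CORTICAL_GRID))
    trials_per_intensity: int = 5
    max_amplitude: float = 500.0  # μV of a full response
    slope: float = 5.0
    noise_sd: float = 10.0  # μV
    muscle: str = "FDI"
    protocol: str = "cortical"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intensity_grid) == 0:
            raise ValidationError("intensity grid is empty")
        grid = np.asarray(self.intensity_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("intensity grid must be strictly increasing")
        if self.trials_per_intensity < 1:
            raise ValidationError("need at least one trial per intensity")


def _band_limited_noise(n: int, sample_rate: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` by DFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValidationError("band too narrow for the requested duration")
    return x / sd


def gen_emg_pair(spec: CommonDriveSpec) -> Recording:
    """Two-channel EMG with in-band coherence κ² by construction."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    c = _band_limited_noise(n, spec.sample_rate, spec.band, rng)
    n1 = _band_limited_noise(n, spec.sample_rate, spec.band, rng)
    n2 = _band_limited_noise(n, spec.sample_rate, spec.band, rng)
    k = spec.common_fraction
    x = np.sqrt(k) * c + np.sqrt(1.0 - k) * n1
    y = np.sqrt(k) * c + np.sqrt(1.0 - k) * n2
    # Same acquisition-style shaping on both channels: coherence-neutral.
    lo = max(spec.emg_band[0], 1e-3)
    hi = min(spec.emg_band[1], 0.999 * spec.sample_rate / 2)
    sos = butter(4, [lo, hi], btype="bandpass", fs=spec.sample_rate, output="sos")
    x = sosfiltfilt(sos, x)
    y = sosfiltfilt(sos, y)
    scale_x = spec.rms_uv / max(x.std(), 1e-30)
    scale_y = spec.rms_uv / max(y.std(), 1e-30)
    x, y = x * scale_x, y * scale_y
    if spec.line_amplitude > 0:
        t = np.arange(n) / spec.sample_rate
        line = spec.line_amplitude * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        x = x + line
        y = y + line
    return Recording(spec.sample_rate, ["emg_1", "emg_2"],
                     np.column_stack([x, y]))


def gen_mve_session(
    envelope_uv: float,
    rest_noise_uv: float,
    trial_duration_s: float = 4.0,
    rest_duration_s: float = 2.0,
    sample_rate: float = 1000.0,
    seed: int = 0,
) -> tuple[Recording, Recording]:
    """An MVE trial of target RMS ``envelope_uv`` plus a rest recording."""
    if envelope_uv < 0 or rest_noise_uv < 0:
        raise ValidationError("amplitudes must be non-negative")
    if trial_duration_s <= 0 or rest_duration_s <= 0:
        raise ValidationError("durations must be positive")
    rng = np.random.default_rng(seed)

    def _make(duration: float, rms: float) -> Recording:
        # Constant-modulus noise: hard-limited band-limited noise keeps the
        # EMG-band zero-crossing statistics while pinning |x| (and hence the
        # rectified RMS of every window) exactly to the target, so a
        # sustained effort reads out as its envelope rather than as the
        # upper tail of a windowed-RMS sampling fluctuation.
        n = int(round(duration * sample_rate))
        g = _band_limited_noise(n, sample_rate, (20.0, 460.0), rng)
        return Recording(sample_rate, ["emg"], rms * np.sign(g))

    return _make(trial_duration_s, envelope_uv), _make(rest_duration_s, rest_noise_uv)


def _response_probability(spec: RecruitmentSpec, intensity: float,
                          threshold_uv: float = 50.0) -> float:
    """Exact P(peak-to-peak >= threshold) under the generating model."""
    from scipy.stats import norm

    p_sig = 1.0 / (1.0 + np.exp(-spec.slope * (intensity - spec.true_threshold)))
    if spec.noise_sd == 0:
        hit_resp = 1.0 if spec.max_amplitude >= threshold_uv else 0.0
        hit_null = 0.0 if threshold_uv > 0 else 1.0
    else:
        hit_resp = norm.sf(threshold_uv, loc=spec.max_amplitude, scale=spec.noise_sd)
        hit_null = norm.sf(threshold_uv, loc=0.0, scale=spec.noise_sd)
    return float(p_sig * hit_resp + (1.0 - p_sig) * hit_null)


def true_rmt(spec: RecruitmentSpec, threshold_uv: float = 50.0) -> float | None:
    """Smallest grid intensity whose generating response probability >= 0.5."""
    for intensity in spec.intensity_grid:
        if _response_probability(spec, intensity, threshold_uv) >= 0.5:
            return float(intensity)
    return None


def gen_mep_session(spec: RecruitmentSpec) -> RecruitmentSession:
    """Simulate a stimulus-response acquisition over the intensity grid."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for intensity in spec.intensity_grid:
        p = 1.0 / (1.0 + np.exp(-spec.slope * (intensity - spec.true_threshold)))
        for _ in range(spec.trials_per_intensity):
            responded = rng.random() < p
            amp = responded * spec.max_amplitude + rng.normal(0.0, spec.noise_sd)
            rows.append({"intensity": float(intensity), "p2p": max(0.0, amp),
                         "kept": True})
    return RecruitmentSession(muscle=spec.muscle, protocol=spec.protocol,
                              trials=pd.DataFrame(rows))


def gen_ssep_session(
    response_uv: float,
    n_stimuli: int = 300,
    rate_hz: float = 3.0,
    noise_uv: float = 20.0,
    sample_rate: float = 4800.0,
    latency_s: float = 0.020,
    response_width_s: float = 0.010,
    window_s: tuple[float, float] = (-0.1, 0.1),
    seed: int = 0,
) -> EpochSet:
    """Stimulus-locked epochs with an optional embedded deflection.

    Noise is band-limited to 0.5–500 Hz (the amplifier passband of the
    emulated EEG) and normalized to ``noise_uv`` RMS; the response, when
    non-zero, is a half-sine deflection of peak ``response_uv`` centred at
    ``latency_s`` after the stimulus, identical in every epoch.
    ``rate_hz`` is bookkeeping only: epochs are generated independently.
    """
    if n_stimuli < 1:
        raise ValidationError("need at least one stimulus")
    if noise_uv < 0 or response_uv < 0:
        raise ValidationError("amplitudes must be non-negative")
    if rate_hz <= 0:
        raise ValidationError("stimulation rate must be positive")
    rng = np.random.default_rng(seed)
    n_samp = int(round((window_s[1] - window_s[0]) * sample_rate))
    noise = _band_limited_noise(
        n_stimuli * n_samp, sample_rate, (0.5, 500.0), rng
    ).reshape(n_stimuli, n_samp) * noise_uv
    epochs = noise
    if response_uv > 0:
        t = np.arange(n_samp) / sample_rate + window_s[0]
        start = latency_s - response_width_s / 2
        phase = (t - start) / response_width_s
        bump = np.where((phase >= 0) & (phase <= 1),
                        np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
        epochs = epochs + response_uv * bump
    meta = pd.DataFrame({
        "intensity": np.nan, "kept": True, "rejection_reason": "",
        "stimulus_rate_hz": rate_hz,
    }, index=range(n_stimuli))
    return EpochSet(epochs, sample_rate, window_s, meta)


def gen_attendance(
    schedule: list[tuple[str, int]] | None = None,
    attendance_rate: float | dict[str, float] = 1.0,
    delays: dict[str, list[float]] | None = None,
    participant: str = "P1",
    stochastic: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """An attendance log over the phase schedule for all outcome groups.

    ``attendance_rate`` is a scalar or per-phase mapping in [0, 1];
    attended sessions are ``round(rate * s)`` (deterministic mode) or a
    binomial draw (stochastic mode).  ``delays`` maps outcome group to a
    per-phase list of assessment delays in weeks (default: all zero).
    """
    schedule = list(schedule) if schedule is not None else list(DEFAULT_SCHEDULE)
    rng = np.random.default_rng(seed)
    rows = []
    for group in OUTCOME_GROUPS:
        group_delays = (delays or {}).get(group, [0.0] * len(schedule))
        if len(group_delays) != len(schedule):
            raise ValidationError("one delay per phase per outcome group required")
        for (phase, s), w in zip(schedule, group_delays):
            rate = (attendance_rate.get(phase, 1.0)
                    if isinstance(attendance_rate, dict) else attendance_rate)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("attendance rate must lie in [0, 1]")
            if w < 0:
                raise ValidationError("delays must be non-negative")
            if s == 0:
                x = 0
            elif stochastic:
                x = int(rng.binomial(s, rate))
            else:
                x = int(round(rate * s))
            rows.append({
                "participant": participant, "phase": phase,
                "outcome_group": group, "scheduled": int(s),
                "attended": x, "delay_weeks": float(w),
            })
    from .io_formats import validate_attendance

    return validate_attendance(pd.DataFrame(rows))
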