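"""Inter-muscular coherence (IMC) with confidence-limit thresholding.

Magnitude-squared coherence between two EMG channels is estimated by
averaging plain (untapered) periodograms over L non-overlapping segments:

    C(f) = |<S_xy>|^2 / (<S_xx> <S_yy>)

Under independence the estimate at a bin exceeds

    CI = 1 - 0.05^(1/(L-1))

with probability 0.05, so bins above CI are deemed significant.  Band
statistics sum the significant coherence values over the beta (15–30 Hz),
low-gamma (30–48 Hz) and high-gamma (52–98 Hz) bands and divide by the
band-width constants 15, 18 and 46.  With the default 1 s segments the
frequency grid is 1 Hz, so the band sums run over integer frequencies;
the inclusive-edge convention (e.g. 16 bins for 15–30 Hz) is the default
and is recorded on the result, with a bin-count divisor available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ValidationError

#: Band name -> (low Hz, high Hz, published normalization divisor).
BANDS: dict[str, tuple[float, float, float]] = {
    "beta": (15.0, 30.0, 15.0),
    "gamma_low": (30.0, 48.0, 18.0),
    "gamma_high": (52.0, 98.0, 46.0),
}


@dataclass
class CoherenceSpectrum:
    """Per-frequency coherence with its estimation context.

    The averaged auto-/cross-spectra are retained so independent
    re-derivations of C(f) can be checked against the estimator.
    """

    frequencies: np.ndarray
    coherence: np.ndarray
    segment_count: int
    segment_len_s: float
    s_xx: np.ndarray
    s_yy: np.ndarray
    s_xy: np.ndarray

    @property
    def confidence_limit(self) -> float:
        return coherence_ci(self.segment_count)

    @property
    def resolution_hz(self) -> float:
        return 1.0 / self.segment_len_s


@dataclass
class BandArea:
    """Band-normalized sum of significant coherence (IMC area)."""

    band: str
    low_hz: float
    high_hz: float
    raw_sum: float
    divisor: float
    area: float
    n_significant_bins: int
    n_band_bins: int


def msc_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate: float,
    segment_len_s: float = 1.0,
) -> CoherenceSpectrum:
    """Periodogram-averaged magnitude-squared coherence.

    The signals are cut into ``L = floor(N / segment_len)`` non-overlapping
    segments (tail samples discarded, no taper, no detrending) and the
    averaged cross- and auto-spectra form C(f).  At least two segments are
    required, otherwise the confidence limit is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    seg = int(round(segment_len_s * sample_rate))
    if seg < 2:
        raise ValidationError("segment length below 2 samples")
    L = x.size // seg
    if L < 2:
        raise ValidationError(
            f"need >= 2 complete segments, got {L} (N={x.size}, seg={seg})"
        )
    xs = x[: L * seg].reshape(L, seg)
    ys = y[: L * seg].reshape(L, seg)
    fx = np.fft.rfft(xs, axis=1)
    fy = np.fft.rfft(ys, axis=1)
    s_xx = np.mean(np.abs(fx) ** 2, axis=0)
    s_yy = np.mean(np.abs(fy) ** 2, axis=0)
    s_xy = np.mean(fx * np.conj(fy), axis=0)
    denom = s_xx * s_yy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(s_xy) ** 2 / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    freqs = np.fft.rfftfreq(seg, d=1.0 / sample_rate)
    return CoherenceSpectrum(
        frequencies=freqs,
        coherence=coh,
        segment_count=L,
        segment_len_s=seg / sample_rate,
        s_xx=s_xx,
        s_yy=s_yy,
        s_xy=s_xy,
    )


def coherence_ci(L: int, alpha: float = 0.05) -> float:
    """95% confidence limit for coherence from L non-overlapping segments."""
    if L < 2:
        raise ValidationError("confidence limit undefined for L < 2")
    return 1.0 - alpha ** (1.0 / (L - 1))


def significant_mask(spec: CoherenceSpectrum) -> np.ndarray:
    """Boolean mask of bins strictly above the confidence limit."""
    return spec.coherence > spec.confidence_limit


def band_area(
    spec: CoherenceSpectrum,
    mask: np.ndarray,
    band: str,
    divisor_convention: str = "printed",
) -> BandArea:
    """Normalized sum of significant coherence over a named band.

    Band edges are inclusive on the frequency grid.  ``divisor_convention``
    selects the published band-width constants (``"printed"``: 15/18/46) or
    the inclusive bin count (``"bin_count"``).  Requires the grid to land
    exactly on the band edges (the default 1 s segments give a 1 Hz grid).
    """
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
    lo, hi, printed = BANDS[band]
    df = spec.resolution_hz
    tol = 1e-9
    if (abs(lo / df - round(lo / df)) > tol) or (abs(hi / df - round(hi / df)) > tol):
        raise ValidationError(
            f"band edges ({lo}, {hi}) Hz not on the {df} Hz frequency grid"
        )
    in_band = (spec.frequencies >= lo - tol) & (spec.frequencies <= hi + tol)
    n_band = int(in_band.sum())
    sel = in_band & np.asarray(mask, dtype=bool)
    raw = float(spec.coherence[sel].sum())
    if divisor_convention == "printed":
        divisor = printed
    elif divisor_convention == "bin_count":
        divisor = float(n_band)
    else:
        raise ValidationError(f"unknown divisor convention {divisor_convention!r}")
    return BandArea(
        band=band,
        low_hz=lo,
        high_hz=hi,
        raw_sum=raw,
        divisor=divisor,
        area=raw / divisor,
        n_significant_bins=int(sel.sum()),
        n_band_bins=n_band,
    )


def band_areas(
    spec: CoherenceSpectrum,
    divisor_convention: str = "printed",
) -> dict[str, BandArea]:
    """All three band areas of the significant-coherence mask."""
    mask = significant_mask(spec)
    return {b: band_area(spec, mask, b, divisor_convention) for b in BANDS}
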