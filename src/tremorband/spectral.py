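"""Welch PSD estimation and the band spectral indices L and F.

The PSD of the trimmed, demeaned, branch-filtered magnitude series is
estimated with a single full-length Hamming window and zero overlap (one
modified periodogram), one-sided, density-scaled with window-power
correction.  From it, two indices are computed per band:

* ``L(f1, f2)`` — the band log-amplitude, the mean of the natural logarithm
  of the PSD over [f1, f2]:  (1/|f2-f1|) * integral of ln PSD(f) df.
* ``F(f1, f2)`` — the power-weighted mean frequency (spectral centroid):
  integral of f*PSD(f) df divided by integral of PSD(f) df, in Hz.

Both integrals are evaluated by the trapezoidal rule on the discrete
frequency grid restricted to the band, edges inclusive.  The low band
(2-4 Hz) is paired with the low-pass branch, the high band (10-20 Hz) with
the high-pass branch; the pairing is fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import TriaxialTrial
from .preprocess import (
    HIGHPASS_10HZ,
    LOWPASS_10HZ,
    FilterSpec,
    MagnitudeSeries,
    Stage,
    demean,
    filter_zero_phase,
    magnitude,
    trim_initial,
)

__all__ = [
    "SpectralEstimate",
    "Band",
    "BandIndices",
    "LOW_BAND",
    "HIGH_BAND",
    "DEFAULT_PSD_FLOOR",
    "welch_psd",
    "band_log_amplitude",
    "band_mean_frequency",
    "extract_indices",
]

logger = logging.getLogger(__name__)

#: Floor applied to PSD bins before taking logarithms, in (m/s²)²/Hz.
DEFAULT_PSD_FLOOR = 1e-20

#: Grid tolerance when selecting band-edge bins (fraction of the grid step).
_EDGE_TOL = 1e-9


@dataclass
class SpectralEstimate:
    """One-sided PSD on the uniform grid 0..fs/2 with step fs/N."""

    frequencies: np.ndarray
    psd: np.ndarray
    n_samples: int
    sampling_rate: float
    window: str = "hamming"
    provenance: tuple[str, str, str] | None = None
    source_stage: Stage | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.frequencies.shape != self.psd.shape:
            raise ValueError("frequencies and psd must have the same shape")
        if not np.all(np.isfinite(self.psd)) or np.any(self.psd < 0):
            raise ValueError("psd values must be finite and non-negative")

    @property
    def grid_step(self) -> float:
        return self.sampling_rate / self.n_samples


@dataclass(frozen=True)
class Band:
    """Analysis band [f1, f2] tied to one filter branch."""

    f1: float
    f2: float
    label: str
    source_stage: Stage

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError("band must satisfy 0 < f1 < f2")

    @property
    def width(self) -> float:
        return self.f2 - self.f1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.f1 + self.f2)


LOW_BAND = Band(2.0, 4.0, "low", Stage.LOWPASSED)
HIGH_BAND = Band(10.0, 20.0, "high", Stage.HIGHPASSED)


@dataclass
class BandIndices:
    """The (L, F) index pair for one band of one trial."""

    L: float
    F: float
    band: Band
    provenance: tuple[str, str, str] | None = None


def welch_psd(series: MagnitudeSeries) -> SpectralEstimate:
    """One-sided Welch PSD with a single full-length Hamming window.

    With window length equal to the series length and zero overlap this is
    the Hamming-modified periodogram; density scaling divides by
    fs * sum(w²), so trapezoid-summed PSD matches the variance of the
    windowed input (Parseval).  Detrending is disabled: the series is
    demeaned upstream and must not be processed twice.
    """
    if series.stage not in (Stage.DEMEANED, Stage.LOWPASSED, Stage.HIGHPASSED):
        raise ValueError(
            "welch_psd expects a demeaned (optionally branch-filtered) "
            f"series, got stage {series.stage.value}"
        )
    n = len(series)
    if n < 16:
        raise ValueError(f"series too short for PSD estimation: {n} < 16")
    freqs, psd = sps.welch(
        series.values,
        fs=series.sampling_rate,
        window="hamming",
        nperseg=n,
        noverlap=0,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    return SpectralEstimate(
        frequencies=freqs,
        psd=psd,
        n_samples=n,
        sampling_rate=series.sampling_rate,
        provenance=series.provenance,
        source_stage=series.stage,
    )


def _band_slice(spec: SpectralEstimate, band: Band) -> np.ndarray:
    tol = _EDGE_TOL * spec.grid_step
    mask = (spec.frequencies >= band.f1 - tol) & (spec.frequencies <= band.f2 + tol)
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError(
            f"band [{band.f1}, {band.f2}] Hz holds fewer than 2 grid points"
        )
    if spec.frequencies[-1] < band.f2 - tol:
        raise ValueError(
            f"band upper edge {band.f2} Hz exceeds the grid maximum "
            f"{spec.frequencies[-1]:g} Hz"
        )
    return idx


def band_log_amplitude(
    spec: SpectralEstimate, band: Band, floor: float = DEFAULT_PSD_FLOOR
) -> float:
    """Band log-amplitude L: mean natural-log PSD over [f1, f2].

    PSD bins below ``floor`` are clamped to it before the logarithm (ln 0 is
    undefined; clamping is logged).  The trapezoidal integral is divided by
    the band width f2 - f1.
    """
    idx = _band_slice(spec, band)
    f = spec.frequencies[idx]
    p = spec.psd[idx]
    n_floored = int(np.count_nonzero(p < floor))
    if n_floored:
        logger.warning(
            "band_log_amplitude: %d/%d PSD bins below floor %.3g in band "
            "[%g, %g] Hz; clamped",
            n_floored,
            len(p),
            floor,
            band.f1,
            band.f2,
        )
        p = np.maximum(p, floor)
    return float(np.trapezoid(np.log(p), f) / band.width)


def band_mean_frequency(spec: SpectralEstimate, band: Band) -> float:
    """Power-weighted mean frequency F over [f1, f2], in Hz.

    Raises if the band carries zero total power (the centroid is undefined).
    """
    idx = _band_slice(spec, band)
    f = spec.frequencies[idx]
    p = spec.psd[idx]
    total = float(np.trapezoid(p, f))
    if total <= 0.0:
        raise ValueError(
            f"zero power in band [{band.f1}, {band.f2}] Hz: mean frequency "
            "is undefined"
        )
    return float(np.trapezoid(f * p, f) / total)


def extract_indices(
    trial: TriaxialTrial,
    drop_seconds: float = 5.0,
    lowpass: FilterSpec = LOWPASS_10HZ,
    highpass: FilterSpec = HIGHPASS_10HZ,
    bands: tuple[Band, ...] = (LOW_BAND, HIGH_BAND),
    floor: float = DEFAULT_PSD_FLOOR,
) -> tuple[BandIndices, ...]:
    """Run the full per-trial chain and return one (L, F) pair per band.

    Chain: magnitude -> trim(drop_seconds) -> demean -> per band, the paired
    filter branch (low band <-> low-pass, high band <-> high-pass) -> Welch
    PSD -> (L, F).  Returns indices in the order of ``bands``.
    """
    if trial.duration < 15.0 - 1e-9:
        warnings.warn(
            f"trial {trial.provenance} lasts {trial.duration:g}s "
            "(15 s expected)",
            stacklevel=2,
        )
    series = demean(trim_initial(magnitude(trial), drop_seconds))
    branch_cache: dict[Stage, SpectralEstimate] = {}
    out = []
    for band in bands:
        if band.source_stage not in branch_cache:
            spec = lowpass if band.source_stage is Stage.LOWPASSED else highpass
            filtered = filter_zero_phase(series, spec)
            branch_cache[band.source_stage] = welch_psd(filtered)
        est = branch_cache[band.source_stage]
        out.append(
            BandIndices(
                L=band_log_amplitude(est, band, floor=floor),
                F=band_mean_frequency(est, band),
                band=band,
                provenance=trial.provenance,
            )
        )
    return tuple(out)
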