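"""Reduction of a tri-axial trial to the analysis-ready magnitude series.

The fixed preprocessing chain is

    magnitude -> trim_initial(5 s) -> demean -> zero-phase Butterworth filter

with a dual-branch filter stage: a 2nd-order low-pass at 10 Hz feeding the
2-4 Hz analysis and the complementary 2nd-order high-pass at 10 Hz feeding
the 10-20 Hz analysis.  Filters are applied forward and backward (zero net
phase; the magnitude response of the single-pass design is squared).  Stage
tags on :class:`MagnitudeSeries` enforce the chain order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import TriaxialTrial

__all__ = [
    "Stage",
    "MagnitudeSeries",
    "FilterSpec",
    "StageError",
    "magnitude",
    "trim_initial",
    "demean",
    "filter_zero_phase",
    "butterworth_amplitude",
    "zero_phase_amplitude",
    "zero_phase_power_gain",
]


class StageError(ValueError):
    """An operation was applied to a series at the wrong pipeline stage."""


class Stage(str, enum.Enum):
    RAW_MAGNITUDE = "raw_magnitude"
    TRIMMED = "trimmed"
    DEMEANED = "demeaned"
    LOWPASSED = "lowpassed"
    HIGHPASSED = "highpassed"


@dataclass
class MagnitudeSeries:
    """Scalar acceleration magnitude time series (m/s²) with provenance."""

    values: np.ndarray
    sampling_rate: float
    provenance: tuple[str, str, str] | None
    stage: Stage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.stage is Stage.RAW_MAGNITUDE and np.any(self.values < 0):
            raise ValueError("raw magnitude values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth branch specification.

    ``order`` is the design order of the single pass; applying it forward and
    backward squares the magnitude response (effective 4th-order roll-off for
    the default order 2) and cancels the phase.  ``padlen`` samples of
    reflected signal extension are used at each edge (``padtype`` as in
    :func:`scipy.signal.filtfilt`); 1000-sample segments make edge transients
    non-negligible at 2 Hz, hence a default much longer than scipy's.
    """

    kind: str  # "lowpass" | "highpass"
    cutoff: float = 10.0
    order: int = 2
    zero_phase: bool = True
    padtype: str = "even"
    padlen: int = 150

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError("kind must be 'lowpass' or 'highpass'")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")

    @property
    def output_stage(self) -> Stage:
        return Stage.LOWPASSED if self.kind == "lowpass" else Stage.HIGHPASSED


LOWPASS_10HZ = FilterSpec(kind="lowpass", cutoff=10.0, order=2)
HIGHPASS_10HZ = FilterSpec(kind="highpass", cutoff=10.0, order=2)


def magnitude(trial: TriaxialTrial) -> MagnitudeSeries:
    """Elementwise Euclidean norm sqrt(ax² + ay² + az²) of the three axes."""
    values = np.sqrt(trial.ax**2 + trial.ay**2 + trial.az**2)
    return MagnitudeSeries(
        values=values,
        sampling_rate=trial.sampling_rate,
        provenance=trial.provenance,
        stage=Stage.RAW_MAGNITUDE,
    )


def trim_initial(series: MagnitudeSeries, drop_seconds: float = 5.0) -> MagnitudeSeries:
    """Drop the initial ``drop_seconds`` (transient adaptation) from a series.

    A 15-s trial at 100 Hz trimmed by the default 5 s retains exactly 1000
    samples (0.1 Hz spectral resolution downstream).
    """
    if series.stage not in (Stage.RAW_MAGNITUDE, Stage.TRIMMED):
        raise StageError(f"cannot trim a series at stage {series.stage.value}")
    if drop_seconds < 0:
        raise ValueError("drop_seconds must be >= 0")
    n_drop = int(round(drop_seconds * series.sampling_rate))
    if n_drop >= len(series):
        raise ValueError(
            f"series duration {series.duration:g}s does not exceed "
            f"drop_seconds={drop_seconds:g}s"
        )
    return replace(series, values=series.values[n_drop:], stage=Stage.TRIMMED)


def demean(series: MagnitudeSeries) -> MagnitudeSeries:
    """Subtract the arithmetic mean (removes the DC / gravity offset)."""
    if series.stage not in (Stage.RAW_MAGNITUDE, Stage.TRIMMED, Stage.DEMEANED):
        raise StageError(f"cannot demean a series at stage {series.stage.value}")
    values = series.values - series.values.mean()
    return replace(series, values=values, stage=Stage.DEMEANED)


def filter_zero_phase(series: MagnitudeSeries, spec: FilterSpec) -> MagnitudeSeries:
    """Forward-backward Butterworth filtering of a demeaned series.

    Output length equals input length; the net magnitude response is the
    square of the single-pass response and the net phase is zero.
    """
    if series.stage is not Stage.DEMEANED:
        raise StageError(
            "filter_zero_phase requires a demeaned series "
            f"(got stage {series.stage.value})"
        )
    nyquist = series.sampling_rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff:g} Hz must be below Nyquist {nyquist:g} Hz"
        )
    b, a = sps.butter(
        spec.order,
        spec.cutoff,
        btype="low" if spec.kind == "lowpass" else "high",
        fs=series.sampling_rate,
    )
    padlen = min(spec.padlen, len(series) - 1)
    padlen = max(padlen, 3 * spec.order)
    if not spec.zero_phase:
        values = sps.lfilter(b, a, series.values)
    else:
        values = sps.filtfilt(
            b, a, series.values, padtype=spec.padtype, padlen=padlen
        )
    return replace(series, values=values, stage=spec.output_stage)


def butterworth_amplitude(
    f: np.ndarray | float,
    cutoff: float,
    order: int = 2,
    kind: str = "lowpass",
    fs: float | None = None,
) -> np.ndarray | float:
    """Analytic single-pass Butterworth amplitude response |H(f)|.

    With ``fs=None`` this is the continuous-time prototype,
    low-pass 1/sqrt(1 + (f/fc)^(2n)).  With ``fs`` given it is the exact
    response of the bilinear-transform digital design (the filter actually
    applied): the normalized frequency becomes tan(pi f/fs)/tan(pi fc/fs),
    which coincides with the prototype at the cutoff and at low frequencies
    but is slightly sharper near the Nyquist rate.
    """
    f_arr = np.asarray(f, dtype=float)
    if fs is None:
        u = f_arr / cutoff
    else:
        u = np.tan(np.pi * f_arr / fs) / np.tan(np.pi * cutoff / fs)
    denom = np.sqrt(1.0 + u ** (2 * order))
    if kind == "lowpass":
        out = 1.0 / denom
    elif kind == "highpass":
        out = u**order / denom
    else:
        raise ValueError("kind must be 'lowpass' or 'highpass'")
    return out if np.ndim(f) else float(out)


def zero_phase_amplitude(
    f: np.ndarray | float, spec: FilterSpec, fs: float | None = None
) -> np.ndarray | float:
    """Amplitude gain |H(f)|² of the forward-backward filter."""
    h = butterworth_amplitude(f, spec.cutoff, spec.order, spec.kind, fs=fs)
    return np.square(h) if np.ndim(f) else float(h) ** 2


def zero_phase_power_gain(
    f: np.ndarray | float, spec: FilterSpec, fs: float | None = None
) -> np.ndarray | float:
    """PSD (power) gain |H(f)|⁴ of the forward-backward filter."""
    g = zero_phase_amplitude(f, spec, fs=fs)
    return np.square(g) if np.ndim(f) else float(g) ** 2
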