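"""Seeded synthetic tremor cohorts with known spectral ground truth.

The generator emulates the cohort design the analysis expects: 50
participants, each recorded for 15 s at 100 Hz in all four cells of the
2 (limb: dominant / non-dominant) x 2 (condition: PRE / POST) within-subject
layout.  Each trial is

    gravity DC (on the z axis)
    + low-band tremor component (2-4 Hz)
    + high-band tremor component (10-20 Hz)
    + broadband per-axis noise floor,

with the tremor components distributed across the three axes by a random
fixed unit direction per trial.

Each band component is band-limited Gaussian noise synthesized in the
frequency domain with an exponentially tilted in-band PSD, exp(a + b*f).
This shape makes both target indices exact closed-form functions of (a, b):
the band-mean ln PSD is a + b*(f1+f2)/2 and the band centroid is the
centroid of exp(b*f) on [f1, f2], so the injected level L and centroid F are
identifiable and independently steerable.  Two analytic corrections make the
injected truth equal the expectation of the pipeline-extracted index:

* the PSD shape is divided by the zero-phase Butterworth power gain |H(f)|^4
  of the paired branch (exact discrete-design closed form), so the
  post-filter spectrum carries the target shape;
* the underlying PSD carries a factor exp(gamma) (Euler-Mascheroni), because
  a single-window periodogram bin is distributed as PSD * chi2(2)/2, whose
  logarithm has expectation ln PSD - gamma.

Default targets give the cell structure typical of an acute proprioceptive
intervention: L(2-4) rising from about -8.7 to -4.9 PRE to POST with the
2-4 Hz centroid falling from about 3.17 to 2.70 Hz, plus a smaller rise in
the 10-20 Hz band; between-subject spreads are the corresponding observed
cell SDs deflated by sqrt(2) (observed SDs include within-subject estimator
noise).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CohortManifest,
    Condition,
    Limb,
    TriaxialTrial,
    parse_condition,
    parse_limb,
    write_manifest,
    write_trial,
)
from .preprocess import FilterSpec, zero_phase_power_gain

__all__ = [
    "BandModel",
    "GeneratorConfig",
    "Cohort",
    "generate_trial",
    "generate_cohort",
    "write_cohort",
    "tilt_for_centroid",
    "tilted_centroid",
    "EULER_GAMMA",
]

EULER_GAMMA = float(np.euler_gamma)

#: Injected band shapes are extended this many Hz beyond each band edge so
#: that window-leakage at a sharp spectral discontinuity does not bias the
#: edge bins of the analysis band.
_BAND_PAD_HZ = 0.5

#: Injected centroids are clipped this fraction of the band width away from
#: the band edges (the centroid of any in-band spectrum lies inside the band).
_CENTROID_MARGIN = 0.05


def tilted_centroid(b: float, f1: float, f2: float) -> float:
    """Centroid of the tilted spectrum exp(b*f) on [f1, f2] (closed form)."""
    if abs(b) < 1e-12:
        return 0.5 * (f1 + f2)
    # integral f*e^(bf) df / integral e^(bf) df, shifted by f1; the positive-
    # tilt branch is normalized by e^(bw) to avoid overflow at steep tilts
    w = f2 - f1
    if b > 0:
        d = np.exp(-b * w)
        return f1 + ((w - 1.0 / b) + d / b) / (1.0 - d)
    e = np.expm1(b * w)
    num = (w - 1.0 / b) * np.exp(b * w) + 1.0 / b
    return f1 + num / e


def tilt_for_centroid(centroid: float, f1: float, f2: float) -> float:
    """Solve for the tilt b such that exp(b*f) on [f1, f2] has the centroid."""
    if not f1 < centroid < f2:
        raise ValueError(
            f"centroid {centroid:g} Hz must lie strictly inside "
            f"[{f1:g}, {f2:g}] Hz"
        )
    hi = 200.0 / (f2 - f1)  # pushes the centroid to within ~0.5% of an edge
    lo = -hi
    return float(brentq(lambda b: tilted_centroid(b, f1, f2) - centroid, lo, hi))


@dataclass(frozen=True)
class BandModel:
    """Per-band generative targets: PSD level, centroid, and their shifts.

    ``level_*`` are band-average ln PSD values (PSD in (m/s²)²/Hz);
    ``centroid_*`` are in Hz.  The PRE target plus the condition shift gives
    the POST target; per-participant offsets are drawn with the given
    between-subject SDs and shared across that participant's four cells.
    """

    f1: float
    f2: float
    label: str
    level_pre: float
    level_shift: float
    centroid_pre: float
    centroid_shift: float
    level_sd: float
    centroid_sd: float
    branch: str  # "lowpass" | "highpass"

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError("band must satisfy 0 < f1 < f2")
        for cond in (Condition.PRE, Condition.POST):
            c = self.centroid(cond)
            if not self.f1 < c < self.f2:
                raise ValueError(
                    f"{cond.value} centroid target {c:g} Hz lies outside "
                    f"({self.f1:g}, {self.f2:g}) Hz"
                )

    def level(self, condition: Condition) -> float:
        shift = self.level_shift if condition is Condition.POST else 0.0
        return self.level_pre + shift

    def centroid(self, condition: Condition) -> float:
        shift = self.centroid_shift if condition is Condition.POST else 0.0
        return self.centroid_pre + shift


def _default_low_band() -> BandModel:
    return BandModel(
        f1=2.0,
        f2=4.0,
        label="low",
        level_pre=-8.66,
        level_shift=3.79,
        centroid_pre=3.165,
        centroid_shift=-0.46,
        level_sd=0.98,
        centroid_sd=0.13,
        branch="lowpass",
    )


def _default_high_band() -> BandModel:
    return BandModel(
        f1=10.0,
        f2=20.0,
        label="high",
        level_pre=-8.975,
        level_shift=1.195,
        centroid_pre=14.46,
        centroid_shift=-0.335,
        level_sd=0.74,
        centroid_sd=0.85,
        branch="highpass",
    )


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic cohort (defaults: the calibrated cohort conditions).

    50 participants x 2 limbs x 2 conditions, 15 s trials at 100 Hz, gravity
    9.81 m/s² on the z axis, broadband noise floor at ln PSD -16 per axis,
    no limb effect (``limb_effect_level`` adds to the non-dominant ln level).
    """

    n_participants: int = 50
    sampling_rate: float = 100.0
    duration: float = 15.0
    seed: int = 0
    low: BandModel | None = field(default_factory=_default_low_band)
    high: BandModel | None = field(default_factory=_default_high_band)
    noise_floor_log: float | None = -16.0
    gravity: float = 9.81
    limb_effect_level: float = 0.0
    filter_cutoff: float = 10.0
    filter_order: int = 2
    max_tilt_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sampling_rate must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def bands(self) -> list[BandModel]:
        return [b for b in (self.low, self.high) if b is not None]

    def branch_spec(self, branch: str) -> FilterSpec:
        return FilterSpec(
            kind=branch, cutoff=self.filter_cutoff, order=self.filter_order
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        for key in ("low", "high"):
            if data.get(key) is not None and not isinstance(data[key], BandModel):
                data[key] = BandModel(**data[key])
        return cls(**data)


def _clip_centroid(c: float, band: BandModel) -> float:
    margin = _CENTROID_MARGIN * (band.f2 - band.f1)
    return float(np.clip(c, band.f1 + margin, band.f2 - margin))


def _band_target_psd(
    freqs: np.ndarray,
    band: BandModel,
    level: float,
    centroid: float,
    config: GeneratorConfig,
) -> np.ndarray:
    """Pre-filter one-sided PSD of one band component on the rfft grid."""
    b = tilt_for_centroid(centroid, band.f1, band.f2)
    a = level + EULER_GAMMA - b * 0.5 * (band.f1 + band.f2)
    nyquist = config.sampling_rate / 2.0
    lo = max(band.f1 - _BAND_PAD_HZ, 0.25 * band.f1)
    hi = min(band.f2 + _BAND_PAD_HZ, nyquist)
    mask = (freqs >= lo) & (freqs <= hi)
    psd = np.zeros_like(freqs)
    gain = zero_phase_power_gain(
        freqs[mask], config.branch_spec(band.branch), fs=config.sampling_rate
    )
    psd[mask] = np.exp(a + b * freqs[mask]) / np.maximum(gain, 1e-12)
    return psd


def _gaussian_from_psd(
    psd: np.ndarray, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Real Gaussian series of length n whose one-sided PSD is ``psd``."""
    scale = np.sqrt(psd * fs * n / 4.0)
    re = rng.standard_normal(len(psd))
    im = rng.standard_normal(len(psd))
    spectrum = scale * (re + 1j * im)
    spectrum[0] = 0.0
    if n % 2 == 0:
        # real-valued Nyquist bin carries all its power in the real part
        spectrum[-1] = np.sqrt(psd[-1] * fs * n / 2.0) * re[-1]
    return np.fft.irfft(spectrum, n=n)


def generate_trial(
    config: GeneratorConfig,
    limb: str | Limb,
    condition: str | Condition,
    rng: np.random.Generator,
    offsets: dict[str, tuple[float, float]] | None = None,
    participant_id: str = "P000",
) -> tuple[TriaxialTrial, list[dict]]:
    """Generate one trial plus its ground-truth rows (one per band).

    ``offsets`` maps band label to (level offset, centroid offset), typically
    the participant's shared random effects; the limb level effect is added
    for the non-dominant limb.  Returns the trial and ground-truth records
    with the injected post-pipeline band-average ln PSD ``level`` and
    centroid ``centroid``.
    """
    limb = parse_limb(limb)
    condition = parse_condition(condition)
    offsets = offsets or {}
    n = config.n_samples
    fs = config.sampling_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    truth: list[dict] = []
    total_psd = np.zeros_like(freqs)
    for band in config.bands:
        d_level, d_centroid = offsets.get(band.label, (0.0, 0.0))
        level = band.level(condition) + d_level
        if limb is Limb.NONDOMINANT:
            level += config.limb_effect_level
        centroid = _clip_centroid(band.centroid(condition) + d_centroid, band)
        total_psd += _band_target_psd(freqs, band, level, centroid, config)
        truth.append(
            {
                "participant": participant_id,
                "limb": limb.value,
                "condition": condition.value,
                "band": band.label,
                "level": level,
                "centroid": centroid,
            }
        )

    tremor = _gaussian_from_psd(total_psd, n, fs, rng)

    # Random fixed tremor direction; the projection on the gravity axis is
    # what the magnitude series measures (to first order in tremor/gravity),
    # so the z component carries the calibrated signal and the in-plane
    # components are scaled relative to it by tan(theta).
    theta = rng.uniform(0.0, np.deg2rad(config.max_tilt_angle_deg))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    ax = tremor * np.tan(theta) * np.cos(phi)
    ay = tremor * np.tan(theta) * np.sin(phi)
    az = tremor.copy()

    if config.noise_floor_log is not None:
        sigma = np.sqrt(np.exp(config.noise_floor_log) * fs / 2.0)
        ax = ax + rng.normal(0.0, sigma, n)
        ay = ay + rng.normal(0.0, sigma, n)
        az = az + rng.normal(0.0, sigma, n)

    az = az + config.gravity

    trial = TriaxialTrial(
        participant_id=participant_id,
        limb=limb,
        condition=condition,
        sampling_rate=fs,
        ax=ax,
        ay=ay,
        az=az,
    )
    return trial, truth


@dataclass
class Cohort:
    """A generated cohort: trials, ground truth, and the matching manifest."""

    trials: list[TriaxialTrial]
    truth: pd.DataFrame
    manifest: CohortManifest
    config: GeneratorConfig


def _participant_rng(seed: int, participant: int, stream: int) -> np.random.Generator:
    """Named substream: (participant index, stream index) under the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(participant, stream))
    )


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate the full crossed cohort: 4 trials per participant.

    Per participant, one shared (level, centroid) offset pair per band is
    drawn from the between-subject distributions and applied in all four
    limb x condition cells; condition shifts and the limb effect come from
    the config.  All randomness derives from ``config.seed`` through named
    (participant, stream) substreams, so cohorts are reproducible and
    extensible.
    """
    config = config or GeneratorConfig()
    trials: list[TriaxialTrial] = []
    truth_rows: list[dict] = []
    manifest_rows: list[dict] = []
    width = max(3, len(str(config.n_participants)))
    for i in range(config.n_participants):
        pid = f"P{i + 1:0{width}d}"
        rng_offsets = _participant_rng(config.seed, i, 0)
        offsets = {
            band.label: (
                rng_offsets.normal(0.0, band.level_sd),
                rng_offsets.normal(0.0, band.centroid_sd),
            )
            for band in config.bands
        }
        for j, (limb, condition) in enumerate(
            (l, c) for l in Limb for c in Condition
        ):
            rng_trial = _participant_rng(config.seed, i, 1 + j)
            trial, rows = generate_trial(
                config, limb, condition, rng_trial, offsets, participant_id=pid
            )
            trials.append(trial)
            truth_rows.extend(rows)
            manifest_rows.append(
                {
                    "participant": pid,
                    "limb": limb.value,
                    "condition": condition.value,
                    "file": f"{pid}_{limb.value}_{condition.value}.csv",
                }
            )
    return Cohort(
        trials=trials,
        truth=pd.DataFrame(truth_rows),
        manifest=CohortManifest(pd.DataFrame(manifest_rows)),
        config=config,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write trial CSVs, ``manifest.csv`` and ``truth.csv`` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trial, file in zip(cohort.trials, cohort.manifest.rows["file"]):
        write_trial(outdir / file, trial)
    write_manifest(outdir / "manifest.csv", cohort.manifest)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
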