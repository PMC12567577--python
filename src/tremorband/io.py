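"""Reading and writing of accelerometer trials and cohort manifests.

Trials are plain delimited text (comma, tab or whitespace; autodetected), one
row per sample, with either three numeric columns (ax, ay, az, in m/s²) or
four (time, ax, ay, az).  A cohort manifest is a CSV with header
``participant,limb,condition,file`` mapping each recording to its factor cell
in the 2 (limb) × 2 (condition) within-subject design.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Limb",
    "Condition",
    "TriaxialTrial",
    "CohortManifest",
    "TrialParseError",
    "TrialValidationError",
    "ManifestError",
    "read_trial",
    "write_trial",
    "read_manifest",
    "write_manifest",
    "G_PER_MS2",
]

#: Conversion factor applied when trial files are declared to be in g units.
G_PER_MS2 = 9.81


class TrialParseError(ValueError):
    """A trial file could not be parsed (malformed row, wrong column count)."""


class TrialValidationError(ValueError):
    """A trial parsed but violated a contract (non-finite values, bad dt)."""


class ManifestError(ValueError):
    """A cohort manifest is malformed (duplicate key, unknown factor token)."""


class Limb(str, enum.Enum):
    DOMINANT = "dominant"
    NONDOMINANT = "nondominant"


class Condition(str, enum.Enum):
    PRE = "PRE"
    POST = "POST"


_LIMB_TOKENS = {
    "dominant": Limb.DOMINANT,
    "dom": Limb.DOMINANT,
    "d": Limb.DOMINANT,
    "nondominant": Limb.NONDOMINANT,
    "non-dominant": Limb.NONDOMINANT,
    "non_dominant": Limb.NONDOMINANT,
    "nondom": Limb.NONDOMINANT,
    "nd": Limb.NONDOMINANT,
}

_CONDITION_TOKENS = {"pre": Condition.PRE, "post": Condition.POST}


def parse_limb(token: str | Limb) -> Limb:
    """Canonicalize a limb label (case-insensitive)."""
    if isinstance(token, Limb):
        return token
    key = str(token).strip().lower()
    if key not in _LIMB_TOKENS:
        raise ManifestError(f"unknown limb token: {token!r}")
    return _LIMB_TOKENS[key]


def parse_condition(token: str | Condition) -> Condition:
    """Canonicalize a condition label (case-insensitive)."""
    if isinstance(token, Condition):
        return token
    key = str(token).strip().lower()
    if key not in _CONDITION_TOKENS:
        raise ManifestError(f"unknown condition token: {token!r}")
    return _CONDITION_TOKENS[key]


@dataclass
class TriaxialTrial:
    """One raw tri-axial accelerometer recording with its factor labels.

    Axes are in m/s² on a uniform time grid at ``sampling_rate`` Hz.
    """

    participant_id: str
    limb: Limb
    condition: Condition
    sampling_rate: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.limb = parse_limb(self.limb)
        self.condition = parse_condition(self.condition)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (self.ax.ndim == self.ay.ndim == self.az.ndim == 1):
            raise TrialValidationError("axis arrays must be one-dimensional")
        if not (len(self.ax) == len(self.ay) == len(self.az) >= 1):
            raise TrialValidationError(
                "axis arrays must have identical length >= 1"
            )
        if not self.sampling_rate > 0:
            raise TrialValidationError("sampling_rate must be > 0")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TrialValidationError(
                    f"non-finite value in {name} at sample {bad}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def t(self) -> np.ndarray:
        """Implicit uniform time grid in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def provenance(self) -> tuple[str, str, str]:
        return (self.participant_id, self.limb.value, self.condition.value)


def _detect_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace


def _is_header(tokens: Sequence[str]) -> bool:
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_trial(
    path: str | Path,
    participant_id: str,
    limb: str | Limb,
    condition: str | Condition,
    sampling_rate: float = 100.0,
    units: str = "ms2",
) -> TriaxialTrial:
    """Read one trial file into a :class:`TriaxialTrial`.

    The file must have 3 numeric columns (ax, ay, az) or 4 (time, ax, ay, az);
    a header row and the delimiter are autodetected.  If a time column is
    present its median step must match ``1/sampling_rate`` within 1%.  Units
    are m/s² unless ``units='g'``, in which case samples are multiplied by
    9.81 explicitly (no silent unit guessing).
    """
    path = Path(path)
    if units not in ("ms2", "g"):
        raise ValueError("units must be 'ms2' or 'g'")
    raw_lines = path.read_text().splitlines()
    rows: list[list[float]] = []
    ncols: int | None = None
    delim: str | None = None
    for lineno, line in enumerate(raw_lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if delim is None and not rows:
            delim = _detect_delimiter(stripped)
        tokens = stripped.split(delim) if delim else stripped.split()
        tokens = [t.strip() for t in tokens if t.strip() != ""]
        if not rows and _is_header(tokens):
            continue
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise TrialParseError(f"{path}: malformed row at line {lineno}: {stripped!r}") from exc
        if ncols is None:
            ncols = len(values)
            if ncols not in (3, 4):
                raise TrialParseError(
                    f"{path}: expected 3 or 4 columns, found {ncols} at line {lineno}"
                )
        elif len(values) != ncols:
            raise TrialParseError(
                f"{path}: inconsistent column count at line {lineno}"
            )
        rows.append(values)
    if not rows:
        raise TrialParseError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    if ncols == 4:
        t = data[:, 0]
        if len(t) >= 2:
            dt = float(np.median(np.diff(t)))
            expected = 1.0 / sampling_rate
            if not np.isfinite(dt) or abs(dt - expected) > 0.01 * expected:
                raise TrialValidationError(
                    f"{path}: median sampling interval {dt:.6g}s deviates more "
                    f"than 1% from 1/{sampling_rate:g}s"
                )
        axes = data[:, 1:4]
    else:
        axes = data
    if units == "g":
        axes = axes * G_PER_MS2
    return TriaxialTrial(
        participant_id=participant_id,
        limb=limb,
        condition=condition,
        sampling_rate=sampling_rate,
        ax=axes[:, 0],
        ay=axes[:, 1],
        az=axes[:, 2],
    )


def write_trial(
    path: str | Path,
    trial: TriaxialTrial,
    include_time: bool = False,
    header: bool = True,
) -> None:
    """Write a trial as CSV at full float precision (round-trip safe)."""
    path = Path(path)
    cols = [trial.ax, trial.ay, trial.az]
    names = ["ax", "ay", "az"]
    if include_time:
        cols.insert(0, trial.t)
        names.insert(0, "time")
    data = np.column_stack(cols)
    hdr = ",".join(names) if header else ""
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=hdr, comments="")


@dataclass
class CohortManifest:
    """Mapping from (participant, limb, condition) cells to trial files.

    The expected design is fully crossed: each participant contributes all
    four limb × condition cells.
    """

    rows: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("participant", "limb", "condition", "file")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows).copy()
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {missing}")
        df["participant"] = df["participant"].astype(str)
        df["limb"] = [parse_limb(x).value for x in df["limb"]]
        df["condition"] = [parse_condition(x).value for x in df["condition"]]
        dup = df.duplicated(subset=["participant", "limb", "condition"])
        if dup.any():
            keys = df.loc[dup, ["participant", "limb", "condition"]]
            raise ManifestError(
                "duplicate manifest key(s): "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def participants(self) -> list[str]:
        return sorted(self.rows["participant"].unique())

    def missing_cells(self) -> dict[str, list[tuple[str, str]]]:
        """Participants lacking any of the 4 limb × condition cells."""
        expected = {
            (limb.value, cond.value) for limb in Limb for cond in Condition
        }
        out: dict[str, list[tuple[str, str]]] = {}
        for pid, grp in self.rows.groupby("participant"):
            have = set(zip(grp["limb"], grp["condition"]))
            lack = sorted(expected - have)
            if lack:
                out[str(pid)] = lack
        return out

    def is_complete(self) -> bool:
        return not self.missing_cells()


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV (header ``participant,limb,condition,file``)."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return CohortManifest(df)


def write_manifest(path: str | Path, manifest: CohortManifest) -> None:
    manifest.rows.to_csv(path, index=False)
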