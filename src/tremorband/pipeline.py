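"""End-to-end orchestration: simulate -> extract -> analyze.

``run_extract`` turns trials (in memory, or resolved through a cohort
manifest) into the long-format indices table with one row per trial x band.
``run_analyze`` produces the publication-style outputs: a descriptives table
(mean +/- SD per design cell, with significance asterisks from the
within-limb PRE vs POST contrasts), one repeated-measures ANOVA per band and
measure (four in total), the Bonferroni-adjusted pairwise contrasts, the
advisory normality screen, and a human-readable text report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CohortManifest, TriaxialTrial, read_manifest, read_trial
from .preprocess import FilterSpec
from .spectral import (
    DEFAULT_PSD_FLOOR,
    HIGH_BAND,
    LOW_BAND,
    Band,
    extract_indices,
)
from .stats import (
    AnovaResult,
    MeasureTable,
    PairwiseResult,
    bonferroni_pairwise,
    normality_screen,
    pairwise_to_frame,
    rm_anova_2x2,
)
from .synthetic import GeneratorConfig

__all__ = ["RunConfig", "AnalysisResults", "run_extract", "run_analyze"]

logger = logging.getLogger(__name__)

INDEX_COLUMNS = [
    "participant",
    "limb",
    "condition",
    "band",
    "f1",
    "f2",
    "L",
    "F",
]


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run (serialized for
    provenance alongside every output directory)."""

    seed: int = 0
    out_dir: str = "results"
    manifest: str | None = None  # None -> simulate
    units: str = "ms2"
    trim_seconds: float = 5.0
    filter_cutoff: float = 10.0
    filter_order: int = 2
    psd_floor: float = DEFAULT_PSD_FLOOR
    alpha: float = 0.05
    n_comparisons: int = 6
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    skip_bad: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig.from_dict(self.generator)
        self.generator.seed = self.seed

    @property
    def lowpass(self) -> FilterSpec:
        return FilterSpec("lowpass", self.filter_cutoff, self.filter_order)

    @property
    def highpass(self) -> FilterSpec:
        return FilterSpec("highpass", self.filter_cutoff, self.filter_order)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["version"] = __version__
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        data.pop("version", None)
        return cls(**data)


def _trials_from_manifest(
    manifest: CohortManifest,
    base_dir: Path,
    config: RunConfig,
) -> Iterable[TriaxialTrial]:
    for row in manifest.rows.itertuples(index=False):
        path = base_dir / row.file
        try:
            yield read_trial(
                path,
                participant_id=row.participant,
                limb=row.limb,
                condition=row.condition,
                sampling_rate=config.generator.sampling_rate,
                units=config.units,
            )
        except (OSError, ValueError) as exc:
            if config.skip_bad:
                logger.warning("skipping unreadable trial %s: %s", path, exc)
                continue
            raise RuntimeError(f"unreadable trial file {path}: {exc}") from exc


def run_extract(
    trials: Sequence[TriaxialTrial] | None = None,
    manifest_path: str | Path | None = None,
    config: RunConfig | None = None,
    bands: tuple[Band, ...] = (LOW_BAND, HIGH_BAND),
) -> pd.DataFrame:
    """Extract the long-format (L, F) indices table, one row per trial x band.

    Input is either a sequence of in-memory trials or a manifest path whose
    ``file`` column is resolved relative to the manifest location.  The
    result is deterministic given the inputs.
    """
    config = config or RunConfig()
    if (trials is None) == (manifest_path is None):
        raise ValueError("provide exactly one of trials or manifest_path")
    if manifest_path is not None:
        manifest_path = Path(manifest_path)
        manifest = read_manifest(manifest_path)
        missing = manifest.missing_cells()
        if missing:
            logger.warning(
                "manifest is incomplete for participant(s): %s",
                sorted(missing),
            )
        trials = _trials_from_manifest(manifest, manifest_path.parent, config)
    rows = []
    for trial in trials:
        indices = extract_indices(
            trial,
            drop_seconds=config.trim_seconds,
            lowpass=config.lowpass,
            highpass=config.highpass,
            bands=bands,
            floor=config.psd_floor,
        )
        for idx in indices:
            rows.append(
                {
                    "participant": trial.participant_id,
                    "limb": trial.limb.value,
                    "condition": trial.condition.value,
                    "band": idx.band.label,
                    "f1": idx.band.f1,
                    "f2": idx.band.f2,
                    "L": idx.L,
                    "F": idx.F,
                }
            )
    df = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    logger.info("extracted %d index rows (%d trials)", len(df), len(df) // max(len(bands), 1))
    return df


@dataclass
class AnalysisResults:
    """All inferential outputs of one cohort analysis."""

    descriptives: pd.DataFrame
    anovas: dict[tuple[str, str], AnovaResult]
    pairwise: dict[tuple[str, str], list[PairwiseResult]]
    normality: dict[tuple[str, str], pd.DataFrame]
    report: str

    def anova_frame(self) -> pd.DataFrame:
        return pd.concat(
            [a.to_frame() for a in self.anovas.values()], ignore_index=True
        )

    def pairwise_frame(self) -> pd.DataFrame:
        frames = []
        for (band, measure), results in self.pairwise.items():
            f = pairwise_to_frame(results)
            f.insert(0, "band", band)
            f.insert(1, "measure", measure)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(outdir / "descriptives.csv", index=False)
        self.anova_frame().to_csv(outdir / "anova.csv", index=False)
        self.pairwise_frame().to_csv(outdir / "pairwise.csv", index=False)
        pd.concat(
            [
                df.assign(band=band, measure=measure)
                for (band, measure), df in self.normality.items()
            ],
            ignore_index=True,
        ).to_csv(outdir / "normality.csv", index=False)
        (outdir / "report.txt").write_text(self.report)


def _band_display(measure: str, band: str, f1: float, f2: float) -> str:
    return f"{measure}({f1:g}-{f2:g})"


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 1e-4 else f"= {p:.4g}"


def run_analyze(
    indices: pd.DataFrame,
    alpha: float = 0.05,
    n_comparisons: int = 6,
) -> AnalysisResults:
    """Analyze a long-format indices table: descriptives, 4 repeated-measures
    ANOVAs (L and F x two bands), pairwise contrasts and the text report."""
    required = {"participant", "limb", "condition", "band", "L", "F"}
    missing = required - set(indices.columns)
    if missing:
        raise ValueError(f"indices table lacks column(s): {sorted(missing)}")
    bands = list(dict.fromkeys(indices["band"]))
    anovas: dict[tuple[str, str], AnovaResult] = {}
    pairwise: dict[tuple[str, str], list[PairwiseResult]] = {}
    normality: dict[tuple[str, str], pd.DataFrame] = {}
    desc_rows = []
    report_lines = [f"tremorband v{__version__} cohort analysis", ""]
    for band in bands:
        sub = indices[indices["band"] == band]
        f1 = float(sub["f1"].iloc[0]) if "f1" in sub else float("nan")
        f2 = float(sub["f2"].iloc[0]) if "f2" in sub else float("nan")
        for measure in ("L", "F"):
            table = MeasureTable.from_long(indices, band, measure)
            key = (band, measure)
            anova = rm_anova_2x2(table)
            contrasts = bonferroni_pairwise(
                table, m=n_comparisons, alpha=alpha
            )
            anovas[key] = anova
            pairwise[key] = contrasts
            normality[key] = normality_screen(table)
            name = _band_display(measure, band, f1, f2)
            sig = {
                c.contrast: c.significant
                for c in contrasts
            }
            row: dict[str, object] = {"measure": name}
            for cond in ("PRE", "POST"):
                for limb in ("dominant", "nondominant"):
                    cell = table.cell(f"{cond}-{limb}")
                    star = ""
                    if cond == "POST" and sig.get(
                        f"PRE-{limb} vs POST-{limb}", False
                    ):
                        star = " *"
                    row[f"{cond} {limb}"] = (
                        f"{cell.mean():.2f} ± {cell.std(ddof=1):.2f}{star}"
                    )
            desc_rows.append(row)

            report_lines.append(f"{name} (n = {anova.n}):")
            for eff in anova.effects.values():
                report_lines.append(
                    f"  {eff.effect}: F({eff.df_num}, {eff.df_den}) = "
                    f"{eff.F:.2f}, p {_fmt_p(eff.p)}, "
                    f"eta_p^2 = {eff.eta_p2:.3f} ({eff.label})"
                )
            if table.dropped:
                report_lines.append(
                    f"  warning: dropped incomplete participant(s): "
                    f"{table.dropped}"
                )
            for c in contrasts:
                flag = " *" if c.significant else ""
                degen = " [degenerate]" if c.degenerate else ""
                report_lines.append(
                    f"  {c.contrast}: diff = {c.mean_diff:+.3f}, "
                    f"t({c.df}) = {c.t:.2f}, p_adj = {c.p_adjusted:.3f}"
                    f"{flag}{degen}"
                )
            report_lines.append("")
    report_lines.append(
        f"Pairwise threshold: raw p < {alpha / n_comparisons:.4g} "
        f"(Bonferroni, m = {n_comparisons}); asterisks mark significant "
        "within-limb PRE vs POST changes."
    )
    descriptives = pd.DataFrame(desc_rows)
    return AnalysisResults(
        descriptives=descriptives,
        anovas=anovas,
        pairwise=pairwise,
        normality=normality,
        report="\n".join(report_lines) + "\n",
    )
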