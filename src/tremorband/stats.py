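"""Within-subject inferential statistics for the 2 x 2 tremor design.

For each band and measure (L or F) the four cells PRE/POST x dominant/
non-dominant are compared with a classical two-way repeated-measures ANOVA:
each 1-df effect is tested against its own effect-by-subject interaction,
F = MS_effect / MS_(effect x subject), with Greenhouse-Geisser epsilon
(identically 1 for 2-level factors, where sphericity cannot be violated),
partial eta squared effect sizes with Cohen labels (0.01 / 0.06 / 0.14),
and Bonferroni-adjusted paired t-tests over all six unordered cell pairs.
Shapiro-Wilk normality screening is advisory only.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "MeasureTable",
    "EffectResult",
    "AnovaResult",
    "PairwiseResult",
    "shapiro_wilk",
    "normality_screen",
    "rm_anova_2x2",
    "gg_epsilon",
    "partial_eta_squared",
    "partial_eta_squared_from_f",
    "cohen_label",
    "bonferroni_pairwise",
    "CELL_LABELS",
    "DEFAULT_N_COMPARISONS",
]

logger = logging.getLogger(__name__)

#: Cell labels in fixed (time, limb) order: axis 0 = PRE/POST, axis 1 =
#: dominant/non-dominant.
CELL_LABELS = (
    ("PRE-dominant", "PRE-nondominant"),
    ("POST-dominant", "POST-nondominant"),
)

#: All unordered pairs of the four cells.
DEFAULT_N_COMPARISONS = 6

_COHEN_CUTOFFS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))


def cohen_label(eta_p2: float) -> str:
    """Cohen's qualitative label for a partial eta squared value."""
    for cutoff, label in _COHEN_CUTOFFS:
        if eta_p2 >= cutoff:
            return label
    return "negligible"


@dataclass
class MeasureTable:
    """Wide 2 x 2 within-subject layout for one measure in one band.

    ``values`` has shape (n, 2, 2): participants x time (PRE, POST) x limb
    (dominant, non-dominant).  Incomplete participants are dropped listwise
    at construction (recorded in ``dropped`` and logged).
    """

    values: np.ndarray
    participants: list[str]
    measure: str = ""
    band: str = ""
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (2, 2):
            raise ValueError("values must have shape (n, 2, 2)")
        if len(self.participants) != self.values.shape[0]:
            raise ValueError("participants and values disagree on n")
        if self.n < 2:
            raise ValueError("at least 2 complete participants are required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cell values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def cell(self, label: str) -> np.ndarray:
        """Per-participant scores for one named cell."""
        for i, row in enumerate(CELL_LABELS):
            for j, name in enumerate(row):
                if name == label:
                    return self.values[:, i, j]
        raise KeyError(label)

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, band: str, measure: str
    ) -> "MeasureTable":
        """Build from a long indices table.

        Expects columns ``participant, limb, condition, band`` plus the
        measure column (``L`` or ``F``).
        """
        sub = df[df["band"] == band]
        wide = sub.pivot_table(
            index="participant",
            columns=["condition", "limb"],
            values=measure,
            aggfunc="first",
        )
        needed = [
            (c, l)
            for c in ("PRE", "POST")
            for l in ("dominant", "nondominant")
        ]
        missing_cols = [k for k in needed if k not in wide.columns]
        if missing_cols:
            raise ValueError(f"indices table lacks cell(s): {missing_cols}")
        complete = wide.dropna(subset=needed)
        dropped = sorted(set(wide.index) - set(complete.index))
        if dropped:
            logger.warning(
                "dropping %d incomplete participant(s) from %s/%s: %s",
                len(dropped),
                band,
                measure,
                dropped,
            )
        values = np.stack(
            [
                np.column_stack(
                    [complete[("PRE", "dominant")], complete[("PRE", "nondominant")]]
                ),
                np.column_stack(
                    [complete[("POST", "dominant")], complete[("POST", "nondominant")]]
                ),
            ],
            axis=1,
        )
        return cls(
            values=values,
            participants=[str(p) for p in complete.index],
            measure=measure,
            band=band,
            dropped=[str(p) for p in dropped],
        )


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p).

    Requires 3 <= n <= 5000; a constant sample is degenerate (W undefined)
    and raises.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n=5000")
    if np.ptp(values) == 0.0:
        raise ValueError("constant sample: W is undefined (degenerate)")
    res = sst.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def normality_screen(table: MeasureTable, mode: str = "cells") -> pd.DataFrame:
    """Advisory Shapiro-Wilk screen, per cell or per difference score.

    ``mode='cells'`` tests each of the 4 cells; ``mode='differences'`` tests
    the 6 pairwise difference scores that enter the paired contrasts.
    Degenerate (constant) samples are reported, not silently dropped.
    """
    if mode not in ("cells", "differences"):
        raise ValueError("mode must be 'cells' or 'differences'")
    rows = []
    if mode == "cells":
        items = [(lab, table.cell(lab)) for row in CELL_LABELS for lab in row]
    else:
        labels = [lab for row in CELL_LABELS for lab in row]
        items = [
            (f"{a} - {b}", table.cell(a) - table.cell(b))
            for a, b in itertools.combinations(labels, 2)
        ]
    for label, sample in items:
        try:
            w, p = shapiro_wilk(sample)
            rows.append({"sample": label, "W": w, "p": p, "degenerate": False})
        except ValueError:
            rows.append(
                {"sample": label, "W": np.nan, "p": np.nan, "degenerate": True}
            )
    return pd.DataFrame(rows)


@dataclass
class EffectResult:
    """One within-subject effect from the 2 x 2 ANOVA."""

    effect: str
    ss_effect: float
    ss_error: float
    df_num: int
    df_den: int
    F: float
    p: float
    gg_epsilon: float
    eta_p2: float
    label: str
    note: str = ""


@dataclass
class AnovaResult:
    """Three within-subject effects: time, limb and their interaction."""

    effects: dict[str, EffectResult]
    n: int
    measure: str = ""
    band: str = ""
    ss_subjects: float = 0.0

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure": self.measure,
                    "band": self.band,
                    "effect": e.effect,
                    "SS_effect": e.ss_effect,
                    "SS_error": e.ss_error,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "F": e.F,
                    "p": e.p,
                    "GG_epsilon": e.gg_epsilon,
                    "eta_p2": e.eta_p2,
                    "effect_size": e.label,
                    "note": e.note,
                }
                for e in self.effects.values()
            ]
        )


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    total = ss_effect + ss_error
    if total == 0.0:
        raise ValueError("both sums of squares are zero: eta_p2 is undefined")
    return ss_effect / total


def partial_eta_squared_from_f(F: float, df_num: int, df_den: int) -> float:
    """Back-compute partial eta squared from an F statistic:
    F*df_num / (F*df_num + df_den)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return (F * df_num) / (F * df_num + df_den)


def gg_epsilon(level_scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one within factor.

    ``level_scores`` has shape (n, k): per-subject scores at the k levels.
    epsilon = tr(M)^2 / ((k-1) tr(M^2)) with M = C S C' for an orthonormal
    contrast basis C and the sample covariance S of the levels; bounded in
    [1/(k-1), 1] and identically 1 for k = 2 (a single difference variance;
    sphericity cannot be violated).
    """
    level_scores = np.asarray(level_scores, dtype=float)
    if level_scores.ndim != 2 or level_scores.shape[1] < 2:
        raise ValueError("level_scores must be (n, k) with k >= 2")
    n, k = level_scores.shape
    if k == 2:
        return 1.0
    # orthonormal contrasts: complete an orthonormal basis against the
    # constant vector and drop it
    basis, _ = np.linalg.qr(
        np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    )
    c = basis[:, 1:].T  # (k-1, k)
    s = np.cov(level_scores, rowvar=False)
    m = c @ s @ c.T
    tr_m = np.trace(m)
    tr_m2 = np.trace(m @ m)
    if tr_m2 == 0.0:
        return 1.0
    eps = tr_m**2 / ((k - 1) * tr_m2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _effect(
    name: str,
    ss_effect: float,
    ss_error: float,
    n: int,
    epsilon: float,
    note: str = "",
) -> EffectResult:
    df_num, df_den = 1, n - 1
    ms_effect = ss_effect / df_num
    ms_error = ss_error / df_den
    if ms_error == 0.0:
        warnings.warn(
            f"zero error sum of squares for effect '{name}'; F is infinite",
            stacklevel=3,
        )
        f_stat = np.inf if ms_effect > 0 else 0.0
        p = 0.0 if ms_effect > 0 else 1.0
    else:
        f_stat = ms_effect / ms_error
        p = float(sst.f.sf(f_stat, epsilon * df_num, epsilon * df_den))
    if ss_effect == 0.0 and ss_error == 0.0:
        # fully degenerate effect (e.g. identical columns): no variance at all
        eta = 0.0
        note = (note + "; " if note else "") + "degenerate: zero effect and error SS"
    else:
        eta = partial_eta_squared(ss_effect, ss_error)
    return EffectResult(
        effect=name,
        ss_effect=ss_effect,
        ss_error=ss_error,
        df_num=df_num,
        df_den=df_den,
        F=float(f_stat),
        p=p,
        gg_epsilon=epsilon,
        eta_p2=eta,
        label=cohen_label(eta),
        note=note,
    )


def rm_anova_2x2(table: MeasureTable) -> AnovaResult:
    """Two-way fully within-subject ANOVA for the 2 x 2 design.

    Classical sum-of-squares decomposition; each effect is tested against
    its own subject interaction.  With two levels per factor, the time main
    effect F equals the squared paired t on limb-averaged POST - PRE scores.
    Greenhouse-Geisser epsilon is reported as 1 for every effect (2-level
    factors; sphericity is not testable) rather than omitted.
    """
    y = table.values  # (n, time, limb)
    n = table.n
    gm = y.mean()
    subj = y.mean(axis=(1, 2))
    t_mean = y.mean(axis=(0, 2))
    l_mean = y.mean(axis=(0, 1))
    tl_mean = y.mean(axis=0)
    ts_mean = y.mean(axis=2)
    ls_mean = y.mean(axis=1)

    ss_time = 2 * n * float(np.sum((t_mean - gm) ** 2))
    ss_limb = 2 * n * float(np.sum((l_mean - gm) ** 2))
    ss_tl = n * float(
        np.sum((tl_mean - t_mean[:, None] - l_mean[None, :] + gm) ** 2)
    )
    ss_subj = 4 * float(np.sum((subj - gm) ** 2))
    ss_ts = 2 * float(
        np.sum((ts_mean - subj[:, None] - t_mean[None, :] + gm) ** 2)
    )
    ss_ls = 2 * float(
        np.sum((ls_mean - subj[:, None] - l_mean[None, :] + gm) ** 2)
    )
    fitted = (
        gm
        + (subj - gm)[:, None, None]
        + (t_mean - gm)[None, :, None]
        + (l_mean - gm)[None, None, :]
        + (tl_mean - t_mean[:, None] - l_mean[None, :] + gm)[None, :, :]
        + (ts_mean - subj[:, None] - t_mean[None, :] + gm)[:, :, None]
        + (ls_mean - subj[:, None] - l_mean[None, :] + gm)[:, None, :]
    )
    ss_tls = float(np.sum((y - fitted) ** 2))

    # snap numerically-zero sums of squares (cancellation noise from exactly
    # repeated cells) to 0 so degenerate effects report F = 0, not 0/0 noise
    ss_total = float(np.sum((y - gm) ** 2))
    tol = 1e-12 * max(ss_total, np.finfo(float).tiny)
    ss_time, ss_limb, ss_tl, ss_ts, ss_ls, ss_tls = (
        0.0 if ss < tol else ss
        for ss in (ss_time, ss_limb, ss_tl, ss_ts, ss_ls, ss_tls)
    )

    note = "epsilon = 1 (2 levels; sphericity not testable)"
    effects = {
        "time": _effect("time", ss_time, ss_ts, n, 1.0, note),
        "limb": _effect("limb", ss_limb, ss_ls, n, 1.0, note),
        "time x limb": _effect("time x limb", ss_tl, ss_tls, n, 1.0, note),
    }
    return AnovaResult(
        effects=effects,
        n=n,
        measure=table.measure,
        band=table.band,
        ss_subjects=ss_subj,
    )


@dataclass
class PairwiseResult:
    """One Bonferroni-adjusted paired contrast between two design cells."""

    contrast: str
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False


def bonferroni_pairwise(
    table: MeasureTable,
    m: int = DEFAULT_N_COMPARISONS,
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Paired t-tests over all six unordered cell pairs, Bonferroni-adjusted.

    Adjusted p = min(1, m * p_raw); the significance flag compares the raw p
    against the working threshold alpha / m (0.05/6 ~ 0.008).  A contrast
    with a zero-variance difference score is reported as degenerate rather
    than dropped: t = 0 when the mean difference is also zero, otherwise
    +/- infinity with p = 0.
    """
    labels = [lab for row in CELL_LABELS for lab in row]
    out: list[PairwiseResult] = []
    threshold = alpha / m
    for a, b in itertools.combinations(labels, 2):
        diff = table.cell(a) - table.cell(b)
        mean_diff = float(diff.mean())
        df = len(diff) - 1
        if np.ptp(diff) == 0.0 and diff.std(ddof=1) == 0.0:
            if mean_diff == 0.0:
                t_stat, p_raw = 0.0, 1.0
            else:
                t_stat = np.inf if mean_diff > 0 else -np.inf
                p_raw = 0.0
            logger.warning(
                "degenerate contrast %s vs %s: zero-variance difference",
                a,
                b,
            )
            degenerate = True
        else:
            res = sst.ttest_rel(table.cell(a), table.cell(b))
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
            degenerate = False
        out.append(
            PairwiseResult(
                contrast=f"{a} vs {b}",
                mean_diff=mean_diff,
                t=t_stat,
                df=df,
                p_raw=p_raw,
                p_adjusted=min(1.0, m * p_raw),
                significant=p_raw < threshold,
                degenerate=degenerate,
            )
        )
    return out


def pairwise_to_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
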