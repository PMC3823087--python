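"""Inferential layer: paired t-tests, the three-way ANOVA, correlations.

The ANOVA decomposes per-cube error indices over the complete 2 x 2
factorial of the design -- illumination shift (same / shift) crossed with
background (absent / present) -- with Cube as an additional main effect:

    eI ~ Cube + Illumination + Background + Illumination:Background

Cube-by-factor interactions are deliberately omitted; with one eI value per
cube x illumination x background cell (16 x 2 x 2 = 64 observations) the
model leaves 45 residual degrees of freedom, which is the error term the
design implies (each cell mean is itself an across-observer aggregate, so
observer noise provides the residual).

All p-values are reported uncorrected by default (the transparent choice
when test families are ill-defined); a Bonferroni multiplier is available
for users who want family-wise control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "TestResult",
    "InferenceError",
    "paired_t",
    "pearson_r",
    "three_way_anova",
    "condition_factors",
]


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_two_tailed: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise InferenceError("p-value outside [0, 1]")


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float | None
    F: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def df_column(self) -> tuple[int, ...]:
        return tuple(r.df for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": r.source, "df": r.df, "ss": r.ss, "F": r.F, "p": r.p}
                for r in self.rows
            ]
        )


def _maybe_bonferroni(p: float, bonferroni: int | None) -> float:
    if bonferroni is None:
        return p
    if bonferroni < 1:
        raise InferenceError("Bonferroni family size must be >= 1")
    return min(1.0, p * bonferroni)


def paired_t(x, y, bonferroni: int | None = None) -> TestResult:
    """Two-tailed paired t-test on per-cube values.

    Differences with zero variance (including x identical to y up to a
    constant) are degenerate and raise rather than returning an infinite
    statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InferenceError("paired_t needs two equal-length 1-D arrays, n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise InferenceError("degenerate variance: all paired differences equal")
    t, p = stats.ttest_rel(x, y)
    return TestResult(
        statistic=float(t),
        df=len(x) - 1,
        p_two_tailed=_maybe_bonferroni(float(p), bonferroni),
        n=len(x),
    )


def pearson_r(x, y, bonferroni: int | None = None) -> TestResult:
    """Sample Pearson correlation with a two-tailed p from the t transform
    (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InferenceError("pearson_r needs two equal-length 1-D arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InferenceError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(r),
        df=len(x) - 2,
        p_two_tailed=_maybe_bonferroni(float(p), bonferroni),
        n=len(x),
    )


def condition_factors(condition: str) -> tuple[str, str]:
    """Map a condition label to its (illumination, background) factor
    levels in the 2 x 2 design."""
    return {
        "baseline": ("same", "absent"),
        "background": ("same", "present"),
        "illumination": ("shift", "absent"),
        "joint": ("shift", "present"),
    }[condition]


def three_way_anova(ei_cells: pd.DataFrame) -> AnovaTable:
    """Fixed-effects ANOVA on error indices over the complete design.

    ``ei_cells`` must hold exactly one row per cube x illumination x
    background cell with columns ``cube``, ``illumination`` (same/shift),
    ``background`` (absent/present) and ``ei``.  Unbalanced or incomplete
    designs raise.  Returns rows (Cube, Illumination, Background,
    Interaction (ill-back), Error, Total) with Type II sums of squares
    (identical to Type I/III here because the design is balanced).
    """
    required = {"cube", "illumination", "background", "ei"}
    if not required <= set(ei_cells.columns):
        raise InferenceError(f"ei_cells needs columns {sorted(required)}")
    counts = ei_cells.groupby(["cube", "illumination", "background"]).size()
    cubes = ei_cells["cube"].unique()
    if (
        len(counts) != len(cubes) * 4
        or (counts != 1).any()
        or ei_cells["illumination"].nunique() != 2
        or ei_cells["background"].nunique() != 2
    ):
        raise InferenceError(
            "need exactly one eI per cube x illumination x background cell"
        )
    if ei_cells["ei"].isna().any():
        raise InferenceError("missing eI values")

    model = smf.ols(
        "ei ~ C(cube) + C(illumination) + C(background) "
        "+ C(illumination):C(background)",
        data=ei_cells,
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def row(label: str, source: str) -> AnovaRow:
        r = table.loc[source]
        return AnovaRow(
            source=label,
            df=int(r["df"]),
            ss=float(r["sum_sq"]),
            F=float(r["F"]) if np.isfinite(r["F"]) else None,
            p=float(r["PR(>F)"]) if np.isfinite(r["PR(>F)"]) else None,
        )

    rows = [
        row("Cube", "C(cube)"),
        row("Illumination", "C(illumination)"),
        row("Background", "C(background)"),
        row("Interaction (ill-back)", "C(illumination):C(background)"),
        AnovaRow(
            "Error",
            int(table.loc["Residual", "df"]),
            float(table.loc["Residual", "sum_sq"]),
            None,
            None,
        ),
    ]
    total_df = int(sum(r.df for r in rows))
    total_ss = float(sum(r.ss for r in rows))
    rows.append(AnovaRow("Total", total_df, total_ss, None, None))
    assert total_df == len(ei_cells) - 1
    return AnovaTable(tuple(rows))
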