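"""End-to-end analysis: cleaning -> constancy metrics -> dispersion ->
inferential statistics, mirroring the study's result tables.

This is the glue the command-line ``constancy run`` sits on; each step is a
thin orchestration of the per-module functions so that library users can
reproduce any slice of the report directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import CleaningReport, clean
from .dispersion import (
    DispersionError,
    fit_ellipse,
    mean_chromaticity,
    palette_density,
    density_sensitivity,
    variability,
)
from .inference import (
    AnovaTable,
    InferenceError,
    condition_factors,
    paired_t,
    pearson_r,
    three_way_anova,
)
from .metrics import (
    MetricsError,
    constancy_prediction,
    error_index,
    match_uv,
    mbr_per_cube,
    split_half_ei,
    DEFAULT_N_SPLITS,
)
from .study_data import CONDITIONS, CubeStimulus, MatchRecord, Palette

__all__ = ["AnalysisReport", "analyze_experiment", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    cleaning: CleaningReport
    constancy: pd.DataFrame  # cube, condition, n, mbr_mean, mbr_sem, ei
    dispersion: pd.DataFrame  # cube, condition, n, mean_u, mean_v, ellipse_*, variability
    ei_cells: pd.DataFrame  # cube, illumination, background, ei
    anova: AnovaTable | None
    ttests: pd.DataFrame
    correlations: pd.DataFrame
    density: pd.DataFrame


def _cube_condition_records(
    records: list[MatchRecord],
) -> dict[str, dict[str, list[MatchRecord]]]:
    out: dict[str, dict[str, list[MatchRecord]]] = {}
    for r in records:
        out.setdefault(r.cube_name, {}).setdefault(r.condition, []).append(r)
    return out


def analyze_experiment(
    matches: list[MatchRecord],
    palette: Palette,
    cubes: list[CubeStimulus],
    n_splits: int = DEFAULT_N_SPLITS,
    split_seed: int = 0,
    radius_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0),
    bonferroni: bool = False,
) -> AnalysisReport:
    """Run the full analysis on (possibly uncleaned) match records."""
    records, cleaning_report = clean(matches, palette)
    by_cube = _cube_condition_records(records)
    cube_by_name = {c.name: c for c in cubes}

    constancy_rows, dispersion_rows, ei_rows = [], [], []
    for cube_name in sorted(by_cube):
        cube = cube_by_name[cube_name]
        conds = by_cube[cube_name]
        base = conds.get("baseline", [])
        for condition in CONDITIONS:
            recs = conds.get(condition, [])
            if not recs:
                logger.warning("no %s records for cube %s", condition, cube_name)
                continue
            booth = recs[0].match_booth
            n = len(recs)
            mean_c = mean_chromaticity(recs, palette, booth)
            var = variability(recs, palette, booth)
            ell_u = ell_v = np.nan
            if n >= 5:
                try:
                    ell = fit_ellipse(match_uv(recs, palette))
                    ell_u, ell_v = ell.center
                except DispersionError as exc:
                    logger.info(
                        "ellipse fit failed for %s/%s: %s", cube_name, condition, exc
                    )
            dispersion_rows.append(
                {
                    "cube": cube_name,
                    "condition": condition,
                    "n": n,
                    "mean_u": mean_c.u,
                    "mean_v": mean_c.v,
                    "ellipse_u": ell_u,
                    "ellipse_v": ell_v,
                    "variability": var,
                }
            )

            mbr_mean = mbr_sem = np.nan
            if condition == "baseline":
                ei = (
                    split_half_ei(base, palette, n_splits=n_splits, seed=split_seed)
                    if len(base) >= 2
                    else np.nan
                )
            elif condition == "background":
                try:
                    pred = constancy_prediction(cube, base, palette, booth)
                    ei = error_index(mean_c, pred)
                except MetricsError as exc:
                    logger.warning("no prediction for %s/%s: %s", cube_name, condition, exc)
                    ei = np.nan
            else:
                try:
                    res = mbr_per_cube(cube, records, palette, condition)
                    mbr_mean, mbr_sem, ei = res.mbr_mean, res.mbr_sem, res.ei
                except MetricsError as exc:
                    logger.warning("no mBR for %s/%s: %s", cube_name, condition, exc)
                    ei = np.nan
            constancy_rows.append(
                {
                    "cube": cube_name,
                    "condition": condition,
                    "n": n,
                    "mbr_mean": mbr_mean,
                    "mbr_sem": mbr_sem,
                    "ei": ei,
                }
            )
            ill, bg = condition_factors(condition)
            ei_rows.append(
                {"cube": cube_name, "illumination": ill, "background": bg, "ei": ei}
            )

    constancy = pd.DataFrame(constancy_rows)
    dispersion = pd.DataFrame(dispersion_rows)
    ei_cells = pd.DataFrame(ei_rows)

    try:
        anova = three_way_anova(ei_cells)
    except InferenceError as exc:
        logger.warning("ANOVA skipped: %s", exc)
        anova = None

    m = 4 if bonferroni else None  # family: the four headline paired tests

    def _pivot(frame: pd.DataFrame, value: str) -> pd.DataFrame:
        return frame.pivot(index="cube", columns="condition", values=value)

    ei_w = _pivot(constancy, "ei")
    var_w = _pivot(dispersion, "variability")
    mbr_w = _pivot(constancy, "mbr_mean")

    ttest_rows = []
    pairs = [
        ("ei", "background", "baseline", ei_w),
        ("ei", "illumination", "baseline", ei_w),
        ("ei", "background", "illumination", ei_w),
        ("ei", "joint", "illumination", ei_w),
        ("mbr", "joint", "illumination", mbr_w),
        ("variability", "illumination", "baseline", var_w),
        ("variability", "background", "baseline", var_w),
        ("variability", "joint", "baseline", var_w),
    ]
    for measure, c1, c2, wide in pairs:
        if c1 not in wide.columns or c2 not in wide.columns:
            continue
        sub = wide[[c1, c2]].dropna()
        try:
            res = paired_t(sub[c1], sub[c2], bonferroni=m)
        except InferenceError as exc:
            logger.info("paired t %s %s-%s skipped: %s", measure, c1, c2, exc)
            continue
        ttest_rows.append(
            {
                "measure": measure,
                "condition_1": c1,
                "condition_2": c2,
                "t": res.statistic,
                "df": res.df,
                "p": res.p_two_tailed,
                "n": res.n,
            }
        )
    ttests = pd.DataFrame(ttest_rows)

    # palette density per cube: disc centered on the mean baseline match,
    # radius = across-cube average baseline variability
    density_rows = []
    radius = float(var_w["baseline"].mean()) if "baseline" in var_w else np.nan
    if np.isfinite(radius) and radius > 0:
        for cube_name in ei_w.index:
            cube = cube_by_name[cube_name]
            booth = cube.home_booth
            try:
                center = mean_chromaticity(
                    by_cube[cube_name]["baseline"], palette, booth
                )
            except (KeyError, DispersionError):
                continue
            row = {
                "cube": cube_name,
                "booth": booth,
                "radius": radius,
                "density": palette_density(palette, booth, center, radius),
            }
            for mult, count in density_sensitivity(
                palette, booth, center, radius, radius_multipliers
            ):
                row[f"density_x{mult:g}"] = count
            density_rows.append(row)
    density = pd.DataFrame(density_rows)

    corr_rows = []
    corr_specs = [
        ("variability", "baseline", "illumination", var_w, var_w),
        ("variability", "baseline", "background", var_w, var_w),
        ("mbr", "illumination", "joint", mbr_w, mbr_w),
    ]
    for measure, c1, c2, w1, w2 in corr_specs:
        if c1 not in w1.columns or c2 not in w2.columns:
            continue
        sub = pd.concat([w1[c1], w2[c2]], axis=1).dropna()
        if len(sub) < 3:
            continue
        try:
            res = pearson_r(sub.iloc[:, 0], sub.iloc[:, 1])
        except InferenceError:
            continue
        corr_rows.append(
            {
                "measure": measure,
                "x": c1,
                "y": c2,
                "r": res.statistic,
                "df": res.df,
                "p": res.p_two_tailed,
                "n": res.n,
            }
        )
    if not density.empty:
        dens = density.set_index("cube")["density"]
        for measure, cond, wide in [
            ("mbr", "illumination", mbr_w),
            ("mbr", "joint", mbr_w),
            ("variability", "illumination", var_w),
            ("variability", "joint", var_w),
        ]:
            if cond not in wide.columns:
                continue
            sub = pd.concat([dens, wide[cond]], axis=1).dropna()
            if len(sub) < 3:
                continue
            try:
                res = pearson_r(sub.iloc[:, 0], sub.iloc[:, 1])
            except InferenceError:
                continue
            corr_rows.append(
                {
                    "measure": measure,
                    "x": "palette_density",
                    "y": cond,
                    "r": res.statistic,
                    "df": res.df,
                    "p": res.p_two_tailed,
                    "n": res.n,
                }
            )
    correlations = pd.DataFrame(corr_rows)

    return AnalysisReport(
        cleaning=cleaning_report,
        constancy=constancy,
        dispersion=dispersion,
        ei_cells=ei_cells,
        anova=anova,
        ttests=ttests,
        correlations=correlations,
        density=density,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cleaning.json").write_text(report.cleaning.to_json() + "\n")
    report.constancy.to_csv(out / "constancy.csv", index=False)
    report.dispersion.to_csv(out / "dispersion.csv", index=False)
    if report.anova is not None:
        report.anova.to_frame().to_csv(out / "anova.csv", index=False)
    report.ttests.to_csv(out / "ttests.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.density.to_csv(out / "density.csv", index=False)
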