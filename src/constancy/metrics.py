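"""Constancy statistics: prediction, modified Brunswick ratio, error index.

The logic of the index: a perfectly color-constant observer would choose
the *same paint chips* across an illuminant shift, so the chromaticity
their choices would take on, re-measured under the matching booth's
illuminant, is the **constancy prediction**.  Both the physical shift
(``phys``: prediction minus baseline mean) and the perceptual shift
(``perc``: an observed match minus baseline mean) are vectors in u'v'
rooted at the average baseline match, and the **modified Brunswick ratio**

    mBR = (perc . phys) / ||phys||^2

is the signed fraction of the physical shift that the observer's match
traversed: 1 = perfect constancy, 0 = no compensation, > 1 =
overcompensation.  Because the reference is the average *baseline match*
(not the cube's own chromaticity), these are relative constancy indices.

The **error index** eI is the atheoretic companion: the u'v' distance
between a condition's average match and the constancy prediction.  Its
noise floor is the baseline **split-half error**: the distance between the
mean matches of two random halves of the baseline data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .colorimetry import Chromaticity, uv_distance
from .study_data import MatchRecord, Palette, CubeStimulus

__all__ = [
    "ShiftVectors",
    "ConstancyResult",
    "MetricsError",
    "match_uv",
    "constancy_prediction",
    "modified_brunswick_ratio",
    "mbr_per_cube",
    "mbr_from_average_match",
    "error_index",
    "split_half_ei",
    "split_half_distance",
]

#: Default number of random partitions averaged by the split-half
#: estimator.  A single split is the study's literal procedure but an
#: unnecessarily noisy estimate; the mean over many converges to a
#: well-defined functional of the data.
DEFAULT_N_SPLITS = 1000


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ShiftVectors:
    """Perceptual and physical shift vectors sharing a baseline origin."""

    reference: Chromaticity
    perc: np.ndarray
    phys: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "perc", np.asarray(self.perc, dtype=float))
        object.__setattr__(self, "phys", np.asarray(self.phys, dtype=float))
        if self.perc.shape != (2,) or self.phys.shape != (2,):
            raise MetricsError("perc and phys must be 2-vectors in u'v'")
        if not (np.all(np.isfinite(self.perc)) and np.all(np.isfinite(self.phys))):
            raise MetricsError("shift vectors must be finite")


@dataclass(frozen=True)
class ConstancyResult:
    cube_name: str
    condition: str
    mbr_mean: float
    mbr_sem: float | None
    ei: float
    n_observers: int

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise MetricsError("n_observers must be >= 1")
        if self.ei < 0:
            raise MetricsError("error index cannot be negative")


def match_uv(records: list[MatchRecord], palette: Palette) -> np.ndarray:
    """(n, 2) u'v' coordinates of each record's chip in its match booth."""
    rows = []
    for r in records:
        if r.chip_id is None:
            raise MetricsError(
                f"record ({r.observer_id}, {r.cube_name}) has no chip; "
                "run cleaning first"
            )
        rows.append(palette.chrom(r.chip_id, r.match_booth).uv)
    return np.array(rows).reshape(len(rows), 2)


def constancy_prediction(
    cube: CubeStimulus,
    baseline_records: list[MatchRecord],
    palette: Palette,
    match_booth: str,
) -> Chromaticity:
    """Trial-weighted mean chromaticity, in ``match_booth``, of the chips
    chosen for this cube in the baseline condition.

    A chip chosen by k observers contributes k times ("average color
    match" averages over matches, not over unique chips).
    """
    recs = [r for r in baseline_records if r.cube_name == cube.name]
    if not recs:
        raise MetricsError(f"no baseline records for cube {cube.name!r}")
    pts = []
    for r in recs:
        if not palette.has_chrom(r.chip_id, match_booth):
            raise MetricsError(
                f"chip {r.chip_id!r} has no measurement in booth {match_booth!r}"
            )
        pts.append(palette.chrom(r.chip_id, match_booth).uv)
    u, v = np.mean(pts, axis=0)
    return Chromaticity(float(u), float(v))


def modified_brunswick_ratio(sv: ShiftVectors) -> float:
    """mBR = (perc . phys) / ||phys||^2 (scalar projection of the
    perceptual shift onto the physical shift, in units of the physical
    shift's length)."""
    denom = float(sv.phys @ sv.phys)
    if denom == 0.0:
        raise MetricsError("undefined index: physical shift has zero length")
    return float(sv.perc @ sv.phys) / denom


def _cube_records(records, cube_name, condition):
    return [
        r for r in records if r.cube_name == cube_name and r.condition == condition
    ]


def mbr_per_cube(
    cube: CubeStimulus,
    records: list[MatchRecord],
    palette: Palette,
    condition: str,
) -> ConstancyResult:
    """Across-observer mean and s.e.m. of per-observer modified Brunswick
    ratios for one cube in a cross-booth condition, plus the error index of
    the condition's average match.

    The reference is the mean baseline match; ``phys`` is the constancy
    prediction minus the reference; each observer's ``perc`` is their match
    chromaticity (in the matching booth) minus the reference.  With fewer
    than 2 observers the s.e.m. is undefined and reported as None.
    """
    if condition not in ("illumination", "joint"):
        raise MetricsError(
            "the constancy index is defined for cross-booth conditions"
        )
    base = _cube_records(records, cube.name, "baseline")
    if not base:
        raise MetricsError(f"no baseline records for cube {cube.name!r}")
    cond = _cube_records(records, cube.name, condition)
    if not cond:
        raise MetricsError(f"no {condition} records for cube {cube.name!r}")
    match_booths = {r.match_booth for r in cond}
    if len(match_booths) != 1:
        raise MetricsError(f"inconsistent match booths for cube {cube.name!r}")
    (match_booth,) = match_booths

    reference = np.mean(match_uv(base, palette), axis=0)
    prediction = constancy_prediction(cube, base, palette, match_booth)
    phys = prediction.uv - reference
    perc = match_uv(cond, palette) - reference

    ref_chrom = Chromaticity(float(reference[0]), float(reference[1]))
    ratios = np.array(
        [
            modified_brunswick_ratio(ShiftVectors(ref_chrom, p, phys))
            for p in perc
        ]
    )
    n = len(ratios)
    sem = float(np.std(ratios, ddof=1) / math.sqrt(n)) if n >= 2 else None
    avg_match = np.mean(match_uv(cond, palette), axis=0)
    return ConstancyResult(
        cube_name=cube.name,
        condition=condition,
        mbr_mean=float(ratios.mean()),
        mbr_sem=sem,
        ei=float(np.hypot(*(avg_match - prediction.uv))),
        n_observers=n,
    )


def mbr_from_average_match(
    cube: CubeStimulus,
    records: list[MatchRecord],
    palette: Palette,
    condition: str,
) -> float:
    """The methods-text variant: one mBR computed from the condition's
    *average* match.  Equal to the mean of the per-observer ratios by
    linearity of the index; exposed so both estimators are available."""
    if condition not in ("illumination", "joint"):
        raise MetricsError(
            "the constancy index is defined for cross-booth conditions"
        )
    base = _cube_records(records, cube.name, "baseline")
    cond = _cube_records(records, cube.name, condition)
    if not base or not cond:
        raise MetricsError(f"missing baseline or {condition} records for {cube.name!r}")
    match_booth = cond[0].match_booth
    reference = np.mean(match_uv(base, palette), axis=0)
    prediction = constancy_prediction(cube, base, palette, match_booth)
    avg = np.mean(match_uv(cond, palette), axis=0)
    sv = ShiftVectors(
        Chromaticity(float(reference[0]), float(reference[1])),
        avg - reference,
        prediction.uv - reference,
    )
    return modified_brunswick_ratio(sv)


def error_index(avg_match: Chromaticity, prediction: Chromaticity) -> float:
    """u'v' distance between the average match and the constancy
    prediction."""
    return uv_distance(avg_match, prediction)


def split_half_distance(
    points: np.ndarray,
    n_splits: int = DEFAULT_N_SPLITS,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean, over random partitions, of the distance between the mean
    coordinates of two equal-as-possible halves of ``points``."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise MetricsError("split-half error needs at least 2 records")
    if n_splits < 1:
        raise MetricsError("n_splits must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    half = n // 2
    total = 0.0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        m1 = pts[perm[:half]].mean(axis=0)
        m2 = pts[perm[half:]].mean(axis=0)
        total += float(np.hypot(*(m1 - m2)))
    return total / n_splits


def split_half_ei(
    baseline_records: list[MatchRecord],
    palette: Palette,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int | None = 0,
) -> float:
    """Baseline error index: split-half distance of the baseline matches.

    Groups are equal-as-possible (sizes differ by at most one, membership
    uniformly at random).  ``n_splits=1`` reproduces the single random
    split of the original procedure; the default averages over
    ``DEFAULT_N_SPLITS`` partitions.
    """
    pts = match_uv(baseline_records, palette)
    return split_half_distance(pts, n_splits, np.random.default_rng(seed))
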