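"""Observer- and trial-level discard rules with an audit trail.

Two stages, mirroring the study's analysis protocol:

1. **Observer level** -- drop every record of observers who either failed
   to record a chip for more than half of their assigned cubes or carry the
   study-supplied ``wrong_location`` flag (systematically writing cube
   colors in the wrong response slot).
2. **Trial level** -- among surviving records, drop trials with
   indecipherable / missing chip notation, trials whose chip has no
   radiometric measurement in the matching booth, and trials judged a
   clearly different, non-adjacent color category by *both* independent
   raters (a single rater's flag is not sufficient).

Wrong-category judgments are inputs in real-data mode (two boolean rater
columns): the original rule is human judgment and is not recovered here.
:func:`surrogate_category_rater` is an automated stand-in used only by
synthetic pipelines so that the discard path is exercised end to end.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .colorimetry import uv_distance
from .study_data import CubeStimulus, MatchRecord, Palette, builtin_booths

__all__ = [
    "CleaningReport",
    "discard_observers",
    "discard_trials",
    "clean",
    "surrogate_category_rater",
    "TRIAL_DISCARD_REASONS",
]

logger = logging.getLogger(__name__)

#: Reasons, in the precedence order they are assigned to a discarded trial.
TRIAL_DISCARD_REASONS = ("indecipherable", "missing_radiometry", "wrong_category")


@dataclass
class CleaningReport:
    n_observers_in: int = 0
    n_observers_discarded: int = 0
    n_trials_in: int = 0
    n_trials_discarded_by_reason: dict[str, int] = field(default_factory=dict)
    n_trials_out: int = 0

    @property
    def n_trials_discarded(self) -> int:
        return sum(self.n_trials_discarded_by_reason.values())

    def percent_discarded(self, reason: str) -> float:
        """Discard percentage for one reason, relative to the trials that
        entered trial-level cleaning."""
        if self.n_trials_in == 0:
            return math.nan
        return 100.0 * self.n_trials_discarded_by_reason.get(reason, 0) / self.n_trials_in

    def validate(self) -> None:
        if self.n_trials_out != self.n_trials_in - self.n_trials_discarded:
            raise ValueError("trial counts do not balance")
        if any(v < 0 for v in self.n_trials_discarded_by_reason.values()):
            raise ValueError("negative discard count")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_observers_in": self.n_observers_in,
                "n_observers_discarded": self.n_observers_discarded,
                "n_observers_out": self.n_observers_in - self.n_observers_discarded,
                "n_trials_in": self.n_trials_in,
                "n_trials_discarded_by_reason": dict(self.n_trials_discarded_by_reason),
                "n_trials_out": self.n_trials_out,
            },
            indent=2,
        )


def _is_missing(record: MatchRecord) -> bool:
    return record.chip_id is None or "indecipherable" in record.flags


def discard_observers(
    records: list[MatchRecord],
) -> tuple[list[MatchRecord], dict[str, int]]:
    """Remove all records of observers failing the task-comprehension rules.

    An observer is discarded for a missing/indecipherable chip notation on
    strictly more than half of their assigned cubes, or for carrying the
    ``wrong_location`` flag on any record.  Returns the retained records and
    a report fragment.
    """
    by_obs: dict[str, list[MatchRecord]] = {}
    for r in records:
        by_obs.setdefault(r.observer_id, []).append(r)
    discarded: set[str] = set()
    for obs, recs in by_obs.items():
        n_missing = sum(_is_missing(r) for r in recs)
        if 2 * n_missing > len(recs):
            discarded.add(obs)
        elif any("wrong_location" in r.flags for r in recs):
            discarded.add(obs)
    kept = [r for r in records if r.observer_id not in discarded]
    if discarded:
        logger.info(
            "discarded %d of %d observers (%s)",
            len(discarded),
            len(by_obs),
            ", ".join(sorted(discarded)[:5]) + ("..." if len(discarded) > 5 else ""),
        )
    return kept, {
        "n_observers_in": len(by_obs),
        "n_observers_discarded": len(discarded),
    }


def discard_trials(
    records: list[MatchRecord], palette: Palette
) -> tuple[list[MatchRecord], dict]:
    """Remove invalid trials from observer-cleaned records.

    Reasons (assigned with this precedence): ``indecipherable`` (missing or
    unreadable chip notation), ``missing_radiometry`` (flagged as such, or
    the chip has no measurement in the matching booth), ``wrong_category``
    (flagged by both raters).  Returns retained records and a report
    fragment with per-reason counts.
    """
    counts = {reason: 0 for reason in TRIAL_DISCARD_REASONS}
    kept: list[MatchRecord] = []
    for r in records:
        if _is_missing(r):
            counts["indecipherable"] += 1
        elif "missing_radiometry" in r.flags or not palette.has_chrom(
            r.chip_id, r.match_booth
        ):
            counts["missing_radiometry"] += 1
        elif {"rater1_wrong_category", "rater2_wrong_category"} <= r.flags:
            counts["wrong_category"] += 1
        else:
            kept.append(r)
    return kept, {
        "n_trials_in": len(records),
        "n_trials_discarded_by_reason": counts,
        "n_trials_out": len(kept),
    }


def clean(
    records: list[MatchRecord], palette: Palette
) -> tuple[list[MatchRecord], CleaningReport]:
    """Run both cleaning stages and assemble the full report."""
    after_obs, obs_frag = discard_observers(records)
    kept, trial_frag = discard_trials(after_obs, palette)
    report = CleaningReport(**obs_frag, **trial_frag)
    report.validate()
    logger.info("cleaning report: %s", report.to_json())
    return kept, report


def surrogate_category_rater(
    record: MatchRecord,
    cube: CubeStimulus,
    palette: Palette,
    hue_sector_width: float = math.pi / 4,
) -> bool:
    """Automated stand-in for the human category raters (simulation only).

    Hue is the angle of a chromaticity around the matching booth's
    illuminant white point.  Color categories are modeled as hue sectors of
    ``hue_sector_width`` radians; a match is flagged as a clearly different,
    non-adjacent category when chip and cube hues differ by more than the
    span of one sector plus its neighbor (> 2 * width, circularly).  A chip
    lying exactly at the white point has no hue and is never flagged.
    """
    if record.chip_id is None:
        return False
    booth = record.match_booth
    white = builtin_booths()[booth].illuminant.uv
    chip_vec = palette.chrom(record.chip_id, booth).uv - white
    cube_booth = booth if booth in cube.chrom_by_booth else record.view_booth
    cube_vec = cube.chrom(cube_booth).uv - white
    if np.allclose(chip_vec, 0) or np.allclose(cube_vec, 0):
        return False
    dh = math.atan2(*chip_vec[::-1]) - math.atan2(*cube_vec[::-1])
    dh = abs((dh + math.pi) % (2 * math.pi) - math.pi)
    return dh > 2 * hue_sector_width
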