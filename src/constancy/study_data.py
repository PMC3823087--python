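"""Experimental data model: booths, palette, cube stimuli, match records.

The experiment this package analyzes is a two-booth asymmetric matching
study: observers pick, from a book of commercial paint chips, the chip that
matches the paint of a colored cube, under a 2 (illuminant shift: absent /
present) x 2 (3-D background: absent / present) design.  Four conditions
result:

* ``baseline``     -- cube and palette in the same booth, no background;
* ``background``   -- same booth, cube embedded in its paired background;
* ``illumination`` -- cube in its home booth, palette in the other booth;
* ``joint``        -- background plus cross-booth matching.

All readers/writers here use plain delimited text (UTF-8, header row):
``matches.csv``, ``palette.csv`` (one row per chip per booth) and
``cubes.csv`` (one row per cube, chromaticity measured in its home booth).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import Chromaticity

__all__ = [
    "BOOTHS",
    "CONDITIONS",
    "SAME_BOOTH_CONDITIONS",
    "CROSS_BOOTH_CONDITIONS",
    "ALLOWED_FLAGS",
    "Booth",
    "PaletteChip",
    "Palette",
    "CubeStimulus",
    "MatchRecord",
    "StudyDataError",
    "builtin_table2",
    "builtin_booths",
    "CounterbalanceScheme",
    "design_assignment",
    "load_matches",
    "save_matches",
    "load_palette",
    "save_palette",
    "load_cubes",
    "save_cubes",
]

logger = logging.getLogger(__name__)

BOOTHS = ("A", "B")
SAME_BOOTH_CONDITIONS = ("baseline", "background")
CROSS_BOOTH_CONDITIONS = ("illumination", "joint")
CONDITIONS = SAME_BOOTH_CONDITIONS + CROSS_BOOTH_CONDITIONS

#: Trial/observer validity flags.  The first four are trial-level; the
#: ``wrong_location`` flag marks observers judged to have systematically
#: recorded cube colors in the wrong response slot (an observer-level,
#: study-supplied judgment).
ALLOWED_FLAGS = frozenset(
    {
        "indecipherable",
        "missing_radiometry",
        "rater1_wrong_category",
        "rater2_wrong_category",
        "wrong_location",
    }
)


class StudyDataError(ValueError):
    pass


@dataclass(frozen=True)
class Booth:
    id: str
    illuminant: Chromaticity

    def __post_init__(self) -> None:
        if self.id not in BOOTHS:
            raise StudyDataError(f"booth id must be one of {BOOTHS}, got {self.id!r}")


#: Measured booth illuminants: ~2600 K and ~4000 K sources.
def builtin_booths() -> dict[str, Booth]:
    return {
        "A": Booth("A", Chromaticity(0.27, 0.53)),
        "B": Booth("B", Chromaticity(0.22, 0.50)),
    }


@dataclass(frozen=True)
class PaletteChip:
    """One paint chip.  The same physical chip has a distinct measured
    chromaticity under each booth's illuminant, keyed by booth id."""

    chip_id: str
    strip_id: str
    chrom_by_booth: dict[str, Chromaticity]

    def chrom(self, booth: str) -> Chromaticity:
        try:
            return self.chrom_by_booth[booth]
        except KeyError:
            raise StudyDataError(
                f"chip {self.chip_id!r} has no measurement in booth {booth!r}"
            ) from None


class Palette:
    """The matching palette: chips grouped into physical strips.

    Construction is permissive (tests and small examples use tiny
    palettes); :meth:`validate` enforces the real-book invariants -- unique
    chip ids and strips of 7 or 8 chips -- and is called by the file loader
    and the synthetic generator.
    """

    def __init__(self, chips: list[PaletteChip]):
        self.chips = list(chips)
        self._by_id = {c.chip_id: c for c in self.chips}
        if len(self._by_id) != len(self.chips):
            raise StudyDataError("chip_ids must be unique")
        self._arrays: dict[str, tuple[list[str], np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.chips)

    def __contains__(self, chip_id: str) -> bool:
        return chip_id in self._by_id

    def chip(self, chip_id: str) -> PaletteChip:
        try:
            return self._by_id[chip_id]
        except KeyError:
            raise StudyDataError(f"unknown chip_id {chip_id!r}") from None

    def chrom(self, chip_id: str, booth: str) -> Chromaticity:
        return self.chip(chip_id).chrom(booth)

    def has_chrom(self, chip_id: str, booth: str) -> bool:
        c = self._by_id.get(chip_id)
        return c is not None and booth in c.chrom_by_booth

    @property
    def strips(self) -> dict[str, list[PaletteChip]]:
        out: dict[str, list[PaletteChip]] = {}
        for c in self.chips:
            out.setdefault(c.strip_id, []).append(c)
        return out

    def uv_array(self, booth: str) -> tuple[list[str], np.ndarray]:
        """Chip ids (sorted) and their (n, 2) u'v' coordinates in a booth,
        restricted to chips measured there.  Cached; used for vectorized
        nearest-chip searches and density counts."""
        if booth not in self._arrays:
            ids = sorted(
                c.chip_id for c in self.chips if booth in c.chrom_by_booth
            )
            arr = np.array(
                [self._by_id[i].chrom_by_booth[booth].uv for i in ids]
            ).reshape(len(ids), 2)
            self._arrays[booth] = (ids, arr)
        return self._arrays[booth]

    def validate(self) -> None:
        for strip_id, members in self.strips.items():
            if len(members) not in (7, 8):
                raise StudyDataError(
                    f"strip {strip_id!r} has {len(members)} chips; "
                    "palette strips hold 7 or 8"
                )


@dataclass(frozen=True)
class CubeStimulus:
    """One painted cube and the background it is paired with.

    ``chrom_by_booth`` holds radiometric measurements of the cube's top
    surface; the home booth (where the cube physically sits) is always
    present.  ``background_chrom`` is measured in the same booth.
    """

    name: str
    home_booth: str
    chrom_by_booth: dict[str, Chromaticity]
    background_name: str
    background_chrom: Chromaticity

    def chrom(self, booth: str) -> Chromaticity:
        try:
            return self.chrom_by_booth[booth]
        except KeyError:
            raise StudyDataError(
                f"cube {self.name!r} has no measurement in booth {booth!r}"
            ) from None


@dataclass(frozen=True)
class MatchRecord:
    """One observer's chip choice for one cube in one condition."""

    observer_id: str
    trial_index: int
    cube_name: str
    condition: str
    view_booth: str
    match_booth: str
    chip_id: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise StudyDataError(f"unknown condition {self.condition!r}")
        if self.trial_index not in (1, 2):
            raise StudyDataError("trial_index must be 1 or 2")
        if self.view_booth not in BOOTHS or self.match_booth not in BOOTHS:
            raise StudyDataError("booths must be 'A' or 'B'")
        bad = set(self.flags) - ALLOWED_FLAGS
        if bad:
            raise StudyDataError(f"unknown flags {sorted(bad)}")
        same = self.view_booth == self.match_booth
        if self.condition in SAME_BOOTH_CONDITIONS and not same:
            raise StudyDataError(
                f"{self.condition} trials view and match in the same booth"
            )
        if self.condition in CROSS_BOOTH_CONDITIONS and same:
            raise StudyDataError(
                f"{self.condition} trials view and match in different booths"
            )


# --- the printed stimulus table -------------------------------------------
# Columns: cube name, home booth, (u, v, cd/m^2), background name, (u, v, cd/m^2).
_TABLE2 = [
    ("Ice blue", "A", 0.27, 0.53, 62.54, "Red", 0.43, 0.53, 14.27),
    ("Dull green", "A", 0.25, 0.54, 21.77, "Dull blue", 0.23, 0.51, 7.19),
    ("Orange", "B", 0.36, 0.54, 45.06, "Surf green", 0.22, 0.53, 12.01),
    ("Dark brown", "B", 0.32, 0.54, 16.61, "Yellow", 0.30, 0.55, 58.64),
    ("Dark green", "A", 0.23, 0.54, 13.74, "Red", 0.43, 0.53, 14.27),
    ("Plum", "A", 0.30, 0.53, 13.48, "Dull blue", 0.23, 0.51, 7.19),
    ("Peach", "B", 0.31, 0.54, 59.50, "Surf green", 0.22, 0.53, 12.01),
    ("Purple", "B", 0.30, 0.52, 28.01, "Yellow", 0.30, 0.55, 58.64),
    ("Gold", "A", 0.30, 0.54, 41.82, "Purple", 0.29, 0.51, 18.47),
    ("Aqua", "A", 0.24, 0.53, 67.15, "Hyper blue", 0.17, 0.46, 3.62),
    ("Gray", "B", 0.28, 0.54, 48.80, "Peach", 0.35, 0.54, 32.38),
    ("Red", "B", 0.42, 0.53, 19.93, "Green", 0.14, 0.55, 5.62),
    ("Yellow", "A", 0.30, 0.55, 71.38, "Purple", 0.29, 0.51, 18.47),
    ("Doeskin", "A", 0.29, 0.53, 48.75, "Hyper blue", 0.17, 0.46, 3.62),
    ("Secure blue", "B", 0.24, 0.52, 19.69, "Peach", 0.35, 0.54, 32.38),
    ("Pink", "B", 0.38, 0.53, 36.15, "Green", 0.14, 0.55, 5.62),
]


def builtin_table2() -> list[CubeStimulus]:
    """The 16 cube stimuli with their measured chromaticities and paired
    backgrounds, as printed in the study description.  Each of the 8
    backgrounds is shared by exactly two cubes in the same booth."""
    return [
        CubeStimulus(
            name=name,
            home_booth=booth,
            chrom_by_booth={booth: Chromaticity(u, v, Y)},
            background_name=bg,
            background_chrom=Chromaticity(bu, bv, bY),
        )
        for name, booth, u, v, Y, bg, bu, bv, bY in _TABLE2
    ]


# --- counterbalanced design ------------------------------------------------

#: Condition order within a location-group rotation.  Trial 1 holds the
#: same-booth conditions, trial 2 the cross-booth ones.
_ROTATION = ("baseline", "background", "illumination", "joint")


class CounterbalanceScheme:
    """Rotates cubes through conditions so that each observer sees 8 of the
    16 cubes (two per condition, never the same cube twice) and a full cycle
    of 8 observers covers every cube x condition cell.

    Cubes are split into their two home-booth location groups (8 each);
    observer ``i`` takes four consecutive cubes (cyclically) from each
    group, assigned to baseline / background / illumination / joint in
    rotation order.
    """

    def __init__(self, cubes: list[CubeStimulus]):
        groups: dict[str, list[CubeStimulus]] = {"A": [], "B": []}
        for c in cubes:
            groups[c.home_booth].append(c)
        sizes = {b: len(g) for b, g in groups.items()}
        if sizes["A"] != sizes["B"] or sizes["A"] < 4:
            raise StudyDataError(
                f"need equal location groups of >= 4 cubes per booth, got {sizes}"
            )
        self.groups = groups
        self.cycle = sizes["A"]

    def assignment(
        self, observer_index: int
    ) -> list[tuple[CubeStimulus, str, str, str, int]]:
        """(cube, condition, view_booth, match_booth, trial_index) tuples
        for one observer."""
        k = observer_index % self.cycle
        out = []
        seen: set[str] = set()
        for booth in BOOTHS:
            group = self.groups[booth]
            other = "B" if booth == "A" else "A"
            for j, condition in enumerate(_ROTATION):
                cube = group[(k + j) % self.cycle]
                if cube.name in seen:
                    raise StudyDataError(
                        f"scheme shows cube {cube.name!r} twice to one observer"
                    )
                seen.add(cube.name)
                cross = condition in CROSS_BOOTH_CONDITIONS
                out.append(
                    (
                        cube,
                        condition,
                        booth,
                        other if cross else booth,
                        2 if cross else 1,
                    )
                )
        return out


def design_assignment(
    observer_index: int, counterbalance_scheme: CounterbalanceScheme
) -> list[tuple[CubeStimulus, str, str, str, int]]:
    """Functional wrapper around :meth:`CounterbalanceScheme.assignment`."""
    return counterbalance_scheme.assignment(observer_index)


# --- delimited-text I/O -----------------------------------------------------

_MATCH_COLUMNS = [
    "observer_id",
    "trial_index",
    "cube_name",
    "condition",
    "view_booth",
    "match_booth",
    "chip_id",
    "flags",
]


def load_matches(path, palette: Palette | None = None) -> list[MatchRecord]:
    """Read match records from delimited text.

    Every row is validated (condition vocabulary, booth consistency per
    condition, duplicate observer/cube pairs, and -- when a palette is
    supplied -- chip ids); the first violation raises with its row number.
    An empty chip_id field is a recorded non-response and loads as None.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_MATCH_COLUMNS) - set(df.columns)
    if missing:
        raise StudyDataError(f"matches file lacks columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"matches file {path} contains no records", stacklevel=2)
        logger.warning("matches file %s contains no records", path)
        return []
    records: list[MatchRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            chip = row.chip_id.strip() or None
            if chip is not None and palette is not None and chip not in palette:
                raise StudyDataError(f"unknown chip_id {chip!r}")
            rec = MatchRecord(
                observer_id=row.observer_id,
                trial_index=int(row.trial_index),
                cube_name=row.cube_name,
                condition=row.condition,
                view_booth=row.view_booth,
                match_booth=row.match_booth,
                chip_id=chip,
                flags=frozenset(f for f in row.flags.split(";") if f),
            )
        except (StudyDataError, ValueError) as exc:
            raise StudyDataError(f"{path}, row {i}: {exc}") from exc
        key = (rec.observer_id, rec.cube_name)
        if key in seen:
            raise StudyDataError(
                f"{path}, row {i}: duplicate (observer, cube) pair {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def save_matches(records: list[MatchRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "observer_id": r.observer_id,
                "trial_index": r.trial_index,
                "cube_name": r.cube_name,
                "condition": r.condition,
                "view_booth": r.view_booth,
                "match_booth": r.match_booth,
                "chip_id": r.chip_id or "",
                "flags": ";".join(sorted(r.flags)),
            }
            for r in records
        ],
        columns=_MATCH_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_palette(path, validate: bool = True) -> Palette:
    """Read ``chip_id,strip_id,booth,u,v,Y`` rows (one per chip per booth)."""
    df = pd.read_csv(path, dtype={"chip_id": str, "strip_id": str, "booth": str})
    chips: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        entry = chips.setdefault(
            row.chip_id, {"strip_id": row.strip_id, "chrom": {}}
        )
        if entry["strip_id"] != row.strip_id:
            raise StudyDataError(
                f"{path}, row {i}: chip {row.chip_id!r} listed in two strips"
            )
        Y = float(row.Y) if "Y" in df.columns and pd.notna(row.Y) else None
        entry["chrom"][row.booth] = Chromaticity(float(row.u), float(row.v), Y)
    palette = Palette(
        [
            PaletteChip(cid, e["strip_id"], e["chrom"])
            for cid, e in chips.items()
        ]
    )
    if validate:
        palette.validate()
    return palette


def save_palette(palette: Palette, path) -> None:
    rows = []
    for chip in sorted(palette.chips, key=lambda c: c.chip_id):
        for booth in sorted(chip.chrom_by_booth):
            ch = chip.chrom_by_booth[booth]
            rows.append(
                {
                    "chip_id": chip.chip_id,
                    "strip_id": chip.strip_id,
                    "booth": booth,
                    "u": f"{ch.u:.6f}",
                    "v": f"{ch.v:.6f}",
                    "Y": "" if ch.Y is None else f"{ch.Y:.4f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cubes(path) -> list[CubeStimulus]:
    """Read a cube table mirroring the printed stimulus description, with
    optional extra ``u_other,v_other`` columns holding the cube measured in
    the non-home booth (written by the simulator)."""
    df = pd.read_csv(path, dtype={"name": str, "booth": str, "background_name": str})
    cubes = []
    for row in df.itertuples(index=False):
        chrom = {row.booth: Chromaticity(float(row.u), float(row.v), float(row.Y))}
        if "u_other" in df.columns and pd.notna(row.u_other):
            other = "B" if row.booth == "A" else "A"
            chrom[other] = Chromaticity(float(row.u_other), float(row.v_other))
        cubes.append(
            CubeStimulus(
                name=row.name,
                home_booth=row.booth,
                chrom_by_booth=chrom,
                background_name=row.background_name,
                background_chrom=Chromaticity(
                    float(row.bg_u), float(row.bg_v), float(row.bg_Y)
                ),
            )
        )
    return cubes


def save_cubes(cubes: list[CubeStimulus], path) -> None:
    rows = []
    for c in cubes:
        home = c.chrom_by_booth[c.home_booth]
        other = "B" if c.home_booth == "A" else "A"
        oc = c.chrom_by_booth.get(other)
        rows.append(
            {
                "name": c.name,
                "booth": c.home_booth,
                "u": f"{home.u:.6f}",
                "v": f"{home.v:.6f}",
                "Y": f"{home.Y:.4f}" if home.Y is not None else "",
                "u_other": f"{oc.u:.6f}" if oc else "",
                "v_other": f"{oc.v:.6f}" if oc else "",
                "background_name": c.background_name,
                "bg_u": f"{c.background_chrom.u:.6f}",
                "bg_v": f"{c.background_chrom.v:.6f}",
                "bg_Y": f"{c.background_chrom.Y:.4f}"
                if c.background_chrom.Y is not None
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
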