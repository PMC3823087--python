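import numpy as np
import pytest

from constancy.colorimetry import Chromaticity
from constancy.study_data import (
    CubeStimulus,
    MatchRecord,
    Palette,
    PaletteChip,
    builtin_table2,
)


def make_palette(points, booth_points=None, strip_id="s1"):
    """Palette from a list of (u, v) pairs; same chromaticity in both
    booths unless ``booth_points`` supplies booth-B coordinates."""
    chips = []
    for i, (u, v) in enumerate(points):
        chrom = {"A": Chromaticity(u, v), "B": Chromaticity(u, v)}
        if booth_points is not None:
            bu, bv = booth_points[i]
            chrom["B"] = Chromaticity(bu, bv)
        chips.append(PaletteChip(f"c{i + 1:03d}", strip_id, chrom))
    return Palette(chips)


def make_record(
    observer="o1",
    cube="Plum",
    condition="baseline",
    chip="c001",
    view=None,
    match=None,
    flags=(),
    trial=None,
):
    cross = condition in ("illumination", "joint")
    view = view or "A"
    if match is None:
        match = ("B" if view == "A" else "A") if cross else view
    return MatchRecord(
        observer_id=observer,
        trial_index=trial or (2 if cross else 1),
        cube_name=cube,
        condition=condition,
        view_booth=view,
        match_booth=match,
        chip_id=chip,
        flags=frozenset(flags),
    )


@pytest.fixture(scope="session")
def table2_cubes():
    return builtin_table2()


@pytest.fixture
def simple_cube():
    return CubeStimulus(
        name="Plum",
        home_booth="A",
        chrom_by_booth={
            "A": Chromaticity(0.30, 0.53, 13.48),
            "B": Chromaticity(0.26, 0.51),
        },
        background_name="Dull blue",
        background_chrom=Chromaticity(0.23, 0.51, 7.19),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
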