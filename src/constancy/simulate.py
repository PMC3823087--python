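"""Synthetic experiments: palette, booths, cubes, and adapting observers.

The study's raw behavioral data and the physical paint palette are not
published, so this module generates complete synthetic experiments with
known ground truth.  The generative model is deliberately minimal:

* **Palette** -- chip chromaticities under booth A are drawn from a mixture
  of Gaussian clusters (commercial palettes sample color space very
  non-uniformly), clipped to a plausible surface-color region, grouped into
  strips of 7 or 8 similar hues, and re-measured under booth B through a
  von Kries illuminant map.
* **Observers** -- an observer viewing a cube forms an internal target
  chromaticity: the cube's measured chromaticity in the viewing booth,
  shifted fraction ``alpha`` of the way toward its von-Kries image under
  the matching booth's illuminant when the booths differ (alpha = 1 is
  perfect constancy, 0 none), shifted by ``beta`` times a
  background-contrast vector when the cube is embedded in its background,
  and perturbed by isotropic bivariate Gaussian noise (sd ``sigma``, plus
  ``sigma_cross`` extra on cross-booth trials, modeling the added
  uncertainty of representing two illuminants at once).  The response is
  the palette chip nearest the target among chips measured in the matching
  booth (ties broken by lowest chip id) -- matching is discretized exactly
  as in the booths.

``alpha``/``beta``/``sigma`` are an operationalization for testability,
not a claim about the original observers; with a sufficiently dense
palette and small noise the analysis pipeline recovers ``alpha`` as the
mean modified Brunswick ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .colorimetry import (
    Chromaticity,
    chromaticity_to_tristimulus,
    tristimulus_to_chromaticity,
    Tristimulus,
)
from .study_data import (
    CounterbalanceScheme,
    CubeStimulus,
    MatchRecord,
    Palette,
    PaletteChip,
    builtin_table2,
    save_cubes,
    save_matches,
    save_palette,
)

__all__ = [
    "ClusterSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "SimulationError",
    "gen_palette",
    "illuminant_map",
    "simulate_observer_match",
    "expected_match",
    "gen_experiment",
    "write_experiment",
]


class SimulationError(ValueError):
    pass


#: Chromaticity region available to matte surface colors under the booth
#: illuminants (box bounding the measured chip cloud).
_GAMUT_U = (0.14, 0.48)
_GAMUT_V = (0.44, 0.58)

# Hunt-Pointer-Estevez cone primaries: the fixed "cone-like" space in which
# the illuminant map scales channels (von Kries).  The white-point mapping
# is exact for any invertible choice; HPE is the classic one.
_M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
_M_HPE_INV = np.linalg.inv(_M_HPE)


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian-mixture description of palette chromatic density."""

    n_clusters: int = 12
    cluster_sd: float = 0.025
    weight_decay: float = 0.85  # geometric weight profile across clusters

    def weights(self) -> np.ndarray:
        w = self.weight_decay ** np.arange(self.n_clusters)
        return w / w.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and design sizes of a synthetic experiment.

    Defaults emulate the study conditions: 1022 chips, 111 observers making
    8 matches each, booth illuminants at u'v' (0.27, 0.53) (~2600 K) and
    (0.22, 0.50) (~4000 K), an adaptation degree matching the reported mean
    constancy level, and match noise on the scale of a few palette steps.
    """

    alpha: float = 0.88  # degree of illuminant adaptation, 0..1.2
    beta: float = 0.0  # background modulation gain (study found ~none)
    sigma: float = 0.008  # per-axis sd of perceptual noise in u'v'
    sigma_cross: float = 0.0  # extra per-axis sd on cross-booth trials
    n_observers: int = 111
    n_chips: int = 1022
    palette_clusters: ClusterSpec = field(default_factory=ClusterSpec)
    illuminants: tuple[tuple[float, float], tuple[float, float]] = (
        (0.27, 0.53),
        (0.22, 0.50),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.2):
            raise SimulationError("alpha must lie in [0, 1.2]")
        if self.sigma < 0 or self.sigma_cross < 0:
            raise SimulationError("noise sd cannot be negative")
        if self.n_observers < 1:
            raise SimulationError("need at least one observer")
        _strip_sizes(self.n_chips)  # raises if not expressible as 7a + 8b

    @property
    def illuminant_chroms(self) -> dict[str, Chromaticity]:
        (ua, va), (ub, vb) = self.illuminants
        return {"A": Chromaticity(ua, va), "B": Chromaticity(ub, vb)}


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free expected matches per cube x condition, plus the
    generating parameters; deterministic given config and seed."""

    alpha: float
    beta: float
    sigma: float
    sigma_cross: float
    expected: dict[tuple[str, str], tuple[float, float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "beta": self.beta,
                "sigma": self.sigma,
                "sigma_cross": self.sigma_cross,
                "expected": {
                    f"{cube}|{cond}": [round(u, 8), round(v, 8)]
                    for (cube, cond), (u, v) in sorted(self.expected.items())
                },
            },
            indent=2,
            sort_keys=True,
        )


@dataclass(frozen=True)
class SimulatedExperiment:
    matches: list[MatchRecord]
    palette: Palette
    cubes: list[CubeStimulus]
    truth: GroundTruth
    config: SimulationConfig


def _strip_sizes(n_chips: int) -> list[int]:
    """Partition a chip count into strips of 7 and 8 (preferring a mix of
    both sizes when the count allows it)."""
    b = n_chips % 7
    a = (n_chips - 8 * b) // 7
    if a < 0:
        raise SimulationError(f"{n_chips} chips cannot form strips of 7 and 8")
    if b == 0 and a >= 8:
        a, b = a - 8, b + 7  # trade 8 sevens for 7 eights so both occur
    return [7] * a + [8] * b


def illuminant_map(
    chrom_A: Chromaticity, illumA: Chromaticity, illumB: Chromaticity
) -> Chromaticity:
    """Predict a surface's chromaticity under booth B from booth A via
    diagonal von Kries scaling in HPE cone space.

    The chromaticity is lifted to tristimulus at its own luminance (unit if
    unset), converted to cone signals, scaled componentwise by the ratio of
    the booth illuminants' cone signals (each at unit luminance), and
    projected back to u'v'.  Maps ``illumA`` to ``illumB`` exactly.
    """
    def _xyz(c: Chromaticity, Y: float | None = None) -> np.ndarray:
        t = chromaticity_to_tristimulus(c, Y=Y)
        return np.array([t.X, t.Y, t.Z])

    lms_a = _M_HPE @ _xyz(illumA, Y=1.0)
    lms_b = _M_HPE @ _xyz(illumB, Y=1.0)
    lms = _M_HPE @ _xyz(chrom_A)
    xyz = _M_HPE_INV @ (lms * (lms_b / lms_a))
    out = tristimulus_to_chromaticity(Tristimulus(*map(float, xyz)))
    return Chromaticity(out.u, out.v, chrom_A.Y)


def _other(booth: str) -> str:
    return "B" if booth == "A" else "A"


def expected_match(
    cube: CubeStimulus, condition: str, config: SimulationConfig
) -> np.ndarray:
    """Internal target chromaticity (before noise and chip snapping) for a
    cube in a condition: the generator's ground truth."""
    view = cube.home_booth
    cross = condition in ("illumination", "joint")
    target = cube.chrom(view).uv.astype(float)
    if cross:
        ill = config.illuminant_chroms
        mapped = illuminant_map(
            cube.chrom(view), ill[view], ill[_other(view)]
        ).uv
        target = (1.0 - config.alpha) * target + config.alpha * mapped
    if condition in ("background", "joint"):
        contrast = cube.background_chrom.uv - config.illuminant_chroms[view].uv
        target = target + config.beta * contrast
    return target


def gen_palette(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Palette:
    """Draw a synthetic paint-chip palette.

    Booth-A chromaticities come from the config's Gaussian-cluster mixture
    (cluster centers themselves drawn within the gamut box), clipped to the
    gamut; strips group chips of neighboring hue, 7 or 8 chips each;
    booth-B chromaticities follow from the von Kries illuminant map.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    spec = config.palette_clusters
    n = config.n_chips
    centers = np.column_stack(
        [
            rng.uniform(_GAMUT_U[0] + 0.03, _GAMUT_U[1] - 0.03, spec.n_clusters),
            rng.uniform(_GAMUT_V[0] + 0.02, _GAMUT_V[1] - 0.01, spec.n_clusters),
        ]
    )
    assignment = rng.choice(spec.n_clusters, size=n, p=spec.weights())
    pts = centers[assignment] + rng.normal(0.0, spec.cluster_sd, (n, 2))
    pts[:, 0] = np.clip(pts[:, 0], *_GAMUT_U)
    pts[:, 1] = np.clip(pts[:, 1], *_GAMUT_V)

    # strips collect chips of similar hue (angle around the palette mean)
    hue = np.arctan2(*(pts - pts.mean(axis=0)).T[::-1])
    order = np.argsort(hue, kind="stable")
    sizes = _strip_sizes(n)
    rng.shuffle(sizes)

    ill = config.illuminant_chroms
    width = len(str(n))
    chips: list[PaletteChip] = []
    pos = 0
    for s, size in enumerate(sizes):
        strip_id = f"s{s + 1:0{len(str(len(sizes)))}d}"
        for idx in order[pos : pos + size]:
            ca = Chromaticity(float(pts[idx, 0]), float(pts[idx, 1]))
            chips.append(
                PaletteChip(
                    chip_id=f"c{idx + 1:0{width}d}",
                    strip_id=strip_id,
                    chrom_by_booth={
                        "A": ca,
                        "B": illuminant_map(ca, ill["A"], ill["B"]),
                    },
                )
            )
        pos += size
    palette = Palette(sorted(chips, key=lambda c: c.chip_id))
    palette.validate()
    return palette


def simulate_observer_match(
    cube: CubeStimulus,
    condition: str,
    palette: Palette,
    config: SimulationConfig,
    rng: np.random.Generator,
    observer_id: str = "obs",
) -> MatchRecord:
    """Simulate one chip choice: target = expected match + noise, snapped
    to the nearest chip measured in the matching booth."""
    if len(palette) == 0:
        raise SimulationError("empty palette")
    view = cube.home_booth
    cross = condition in ("illumination", "joint")
    match_booth = _other(view) if cross else view
    target = expected_match(cube, condition, config)
    sd = config.sigma + (config.sigma_cross if cross else 0.0)
    if sd > 0:
        target = target + rng.normal(0.0, sd, 2)
    ids, arr = palette.uv_array(match_booth)
    if not ids:
        raise SimulationError(f"no chips measured in booth {match_booth!r}")
    chosen = ids[int(np.argmin(((arr - target) ** 2).sum(axis=1)))]
    return MatchRecord(
        observer_id=observer_id,
        trial_index=2 if cross else 1,
        cube_name=cube.name,
        condition=condition,
        view_booth=view,
        match_booth=match_booth,
        chip_id=chosen,
    )


def _cubes_with_both_booths(config: SimulationConfig) -> list[CubeStimulus]:
    ill = config.illuminant_chroms
    out = []
    for c in builtin_table2():
        home = c.home_booth
        chrom = dict(c.chrom_by_booth)
        chrom[_other(home)] = illuminant_map(
            c.chrom(home), ill[home], ill[_other(home)]
        )
        out.append(
            CubeStimulus(
                name=c.name,
                home_booth=home,
                chrom_by_booth=chrom,
                background_name=c.background_name,
                background_chrom=c.background_chrom,
            )
        )
    return out


def gen_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Build the counterbalanced design and simulate every match.

    Per-observer random streams are derived from the root seed by
    counter-based spawning, so increasing ``n_observers`` extends the
    observer list without reshuffling earlier observers.
    """
    palette = gen_palette(config)
    cubes = _cubes_with_both_booths(config)
    scheme = CounterbalanceScheme(cubes)
    matches: list[MatchRecord] = []
    for i in range(config.n_observers):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, i))
        )
        obs_id = f"obs{i + 1:04d}"
        for cube, condition, _view, _match, _trial in scheme.assignment(i):
            matches.append(
                simulate_observer_match(
                    cube, condition, palette, config, rng, observer_id=obs_id
                )
            )
    truth = GroundTruth(
        alpha=config.alpha,
        beta=config.beta,
        sigma=config.sigma,
        sigma_cross=config.sigma_cross,
        expected={
            (cube.name, cond): tuple(expected_match(cube, cond, config))
            for cube in cubes
            for cond in ("baseline", "background", "illumination", "joint")
        },
    )
    return SimulatedExperiment(matches, palette, cubes, truth, config)


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write matches.csv, palette.csv, cubes.csv, truth.json and a config
    echo; byte-identical for identical config and seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_matches(exp.matches, out / "matches.csv")
    save_palette(exp.palette, out / "palette.csv")
    save_cubes(exp.cubes, out / "cubes.csv")
    (out / "truth.json").write_text(exp.truth.to_json() + "\n")
    cfg = asdict(exp.config)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
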