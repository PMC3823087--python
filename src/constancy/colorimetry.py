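"""Colorimetric primitives: spectra, tristimulus values, and CIE 1976 u'v'.

Every downstream statistic in this package is computed on chromaticity
coordinates in the CIE 1976 uniform chromaticity scale (u', v').  The
``uvY`` coordinates printed for the booths and stimuli sit on the Planckian
locus in u'v' (not in the older CIE 1960 uv), so u'v' is the interpretation
used throughout; fields are nevertheless named ``u`` and ``v`` to match the
conventional shorthand of the experimental literature.

The CIE 1931 2-degree standard-observer color-matching functions are carried
as module constants at 5 nm resolution (380-780 nm) and interpolated
linearly onto whatever wavelength grid a measured spectrum uses.  Spectral
integration is a rectangle rule on the spectrum's own grid: radiometer
output is already discretized and none of the downstream statistics is
sensitive to quadrature refinements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralPowerDistribution",
    "Tristimulus",
    "Chromaticity",
    "spd_to_tristimulus",
    "tristimulus_to_chromaticity",
    "chromaticity_to_tristimulus",
    "uv_distance",
    "CMF_WAVELENGTHS",
    "CMF_XYZ",
    "MAX_LUMINOUS_EFFICACY",
]


class ColorimetryError(ValueError):
    """Degenerate colorimetric input (zero spectrum, zero denominator, ...)."""


# CIE 1931 2-degree standard observer, 380-780 nm at 5 nm steps.
# Columns: xbar, ybar, zbar.
_CMF_TABLE = np.array([
    [380, 0.001368, 0.000039, 0.006450],
    [385, 0.002236, 0.000064, 0.010550],
    [390, 0.004243, 0.000120, 0.020050],
    [395, 0.007650, 0.000217, 0.036210],
    [400, 0.014310, 0.000396, 0.067850],
    [405, 0.023190, 0.000640, 0.110200],
    [410, 0.043510, 0.001210, 0.207400],
    [415, 0.077630, 0.002180, 0.371300],
    [420, 0.134380, 0.004000, 0.645600],
    [425, 0.214770, 0.007300, 1.039050],
    [430, 0.283900, 0.011600, 1.385600],
    [435, 0.328500, 0.016840, 1.622960],
    [440, 0.348280, 0.023000, 1.747060],
    [445, 0.348060, 0.029800, 1.782600],
    [450, 0.336200, 0.038000, 1.772110],
    [455, 0.318700, 0.048000, 1.744100],
    [460, 0.290800, 0.060000, 1.669200],
    [465, 0.251100, 0.073900, 1.528100],
    [470, 0.195360, 0.090980, 1.287640],
    [475, 0.142100, 0.112600, 1.041900],
    [480, 0.095640, 0.139020, 0.812950],
    [485, 0.057950, 0.169300, 0.616200],
    [490, 0.032010, 0.208020, 0.465180],
    [495, 0.014700, 0.258600, 0.353300],
    [500, 0.004900, 0.323000, 0.272000],
    [505, 0.002400, 0.407300, 0.212300],
    [510, 0.009300, 0.503000, 0.158200],
    [515, 0.029100, 0.608200, 0.111700],
    [520, 0.063270, 0.710000, 0.078250],
    [525, 0.109600, 0.793200, 0.057250],
    [530, 0.165500, 0.862000, 0.042160],
    [535, 0.225750, 0.914850, 0.029840],
    [540, 0.290400, 0.954000, 0.020300],
    [545, 0.359700, 0.980300, 0.013400],
    [550, 0.433450, 0.994950, 0.008750],
    [555, 0.512050, 1.000000, 0.005750],
    [560, 0.594500, 0.995000, 0.003900],
    [565, 0.678400, 0.978600, 0.002750],
    [570, 0.762100, 0.952000, 0.002100],
    [575, 0.842500, 0.915400, 0.001800],
    [580, 0.916300, 0.870000, 0.001650],
    [585, 0.978600, 0.816300, 0.001400],
    [590, 1.026300, 0.757000, 0.001100],
    [595, 1.056700, 0.694900, 0.001000],
    [600, 1.062200, 0.631000, 0.000800],
    [605, 1.045600, 0.566800, 0.000600],
    [610, 1.002600, 0.503000, 0.000340],
    [615, 0.938400, 0.441200, 0.000240],
    [620, 0.854450, 0.381000, 0.000190],
    [625, 0.751400, 0.321000, 0.000100],
    [630, 0.642400, 0.265000, 0.000050],
    [635, 0.541900, 0.217000, 0.000030],
    [640, 0.447900, 0.175000, 0.000020],
    [645, 0.360800, 0.138200, 0.000010],
    [650, 0.283500, 0.107000, 0.000000],
    [655, 0.218700, 0.081600, 0.000000],
    [660, 0.164900, 0.061000, 0.000000],
    [665, 0.121200, 0.044580, 0.000000],
    [670, 0.087400, 0.032000, 0.000000],
    [675, 0.063600, 0.023200, 0.000000],
    [680, 0.046770, 0.017000, 0.000000],
    [685, 0.032900, 0.011920, 0.000000],
    [690, 0.022700, 0.008210, 0.000000],
    [695, 0.015840, 0.005723, 0.000000],
    [700, 0.011359, 0.004102, 0.000000],
    [705, 0.008111, 0.002929, 0.000000],
    [710, 0.005790, 0.002091, 0.000000],
    [715, 0.004109, 0.001484, 0.000000],
    [720, 0.002899, 0.001047, 0.000000],
    [725, 0.002049, 0.000740, 0.000000],
    [730, 0.001440, 0.000520, 0.000000],
    [735, 0.001000, 0.000361, 0.000000],
    [740, 0.000690, 0.000249, 0.000000],
    [745, 0.000476, 0.000172, 0.000000],
    [750, 0.000332, 0.000120, 0.000000],
    [755, 0.000235, 0.000085, 0.000000],
    [760, 0.000166, 0.000060, 0.000000],
    [765, 0.000117, 0.000042, 0.000000],
    [770, 0.000083, 0.000030, 0.000000],
    [775, 0.000059, 0.000021, 0.000000],
    [780, 0.000042, 0.000015, 0.000000],
])

CMF_WAVELENGTHS = _CMF_TABLE[:, 0].copy()
CMF_XYZ = _CMF_TABLE[:, 1:].copy()

#: K_m, lm/W; converts radiance-weighted ybar integrals to cd/m^2.
MAX_LUMINOUS_EFFICACY = 683.002

_CMF_SUPPORT = (float(CMF_WAVELENGTHS[0]), float(CMF_WAVELENGTHS[-1]))
_SPD_RANGE = (360.0, 830.0)


@dataclass(frozen=True)
class SpectralPowerDistribution:
    """A sampled spectrum: strictly increasing wavelengths (nm) and
    non-negative spectral power per sample."""

    wavelengths: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "power", p)
        if wl.ndim != 1 or p.ndim != 1 or wl.shape != p.shape:
            raise ColorimetryError("wavelengths and power must be equal-length 1-D arrays")
        if wl.size < 2:
            raise ColorimetryError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ColorimetryError("wavelengths must be strictly increasing")
        if wl[0] < _SPD_RANGE[0] or wl[-1] > _SPD_RANGE[1]:
            raise ColorimetryError(f"wavelengths must lie within {_SPD_RANGE} nm")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ColorimetryError("power must be finite and non-negative")


@dataclass(frozen=True)
class Tristimulus:
    """CIE 1931 2-degree X, Y, Z; Y is in cd/m^2 when the source spectrum
    was absolute spectral radiance."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        for v in (self.X, self.Y, self.Z):
            if not math.isfinite(v):
                raise ColorimetryError("tristimulus values must be finite")
        if self.Y < 0:
            raise ColorimetryError("Y must be non-negative")


@dataclass(frozen=True)
class Chromaticity:
    """A point in the CIE 1976 u'v' plane, optionally carrying luminance."""

    u: float
    v: float
    Y: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 0.7 and 0.0 <= self.v <= 0.7):
            raise ColorimetryError(f"(u, v) = ({self.u}, {self.v}) outside [0, 0.7]^2")

    @property
    def uv(self) -> np.ndarray:
        return np.array([self.u, self.v])


def spd_to_tristimulus(spd: SpectralPowerDistribution) -> Tristimulus:
    """Integrate a spectrum against the 2-degree color-matching functions.

    The CMFs are linearly interpolated onto the spectrum's wavelength grid
    and summed with rectangle-rule bin widths taken from that grid.  The
    result is scaled by K_m = 683 lm/W so that Y is in cd/m^2 for absolute
    spectral radiance input.
    """
    wl, p = spd.wavelengths, spd.power
    if np.all(p == 0):
        raise ColorimetryError("degenerate measurement: spectral power is all zero")
    lo, hi = _CMF_SUPPORT
    if wl[0] < lo or wl[-1] > hi:
        raise ColorimetryError(
            f"wavelengths outside CMF support [{lo:g}, {hi:g}] nm"
        )
    cmf = np.stack(
        [np.interp(wl, CMF_WAVELENGTHS, CMF_XYZ[:, i]) for i in range(3)], axis=1
    )
    widths = np.gradient(wl)
    X, Y, Z = MAX_LUMINOUS_EFFICACY * (cmf * (p * widths)[:, None]).sum(axis=0)
    return Tristimulus(float(X), float(Y), float(Z))


def tristimulus_to_chromaticity(t: Tristimulus) -> Chromaticity:
    """CIE 1976 u' = 4X / (X + 15Y + 3Z), v' = 9Y / (X + 15Y + 3Z).

    Luminance Y is carried through unchanged.
    """
    denom = t.X + 15.0 * t.Y + 3.0 * t.Z
    if denom <= 0:
        raise ColorimetryError("X + 15Y + 3Z must be positive")
    return Chromaticity(4.0 * t.X / denom, 9.0 * t.Y / denom, t.Y)


def chromaticity_to_tristimulus(c: Chromaticity, Y: float | None = None) -> Tristimulus:
    """Invert the u'v' projection at a given luminance (default: the
    chromaticity's own Y, else 1).  Inverse companion of
    :func:`tristimulus_to_chromaticity`."""
    if Y is None:
        Y = c.Y if c.Y is not None else 1.0
    denom = 6.0 * c.u - 16.0 * c.v + 12.0
    if denom <= 0 or c.v <= 0:
        raise ColorimetryError("chromaticity cannot be lifted to tristimulus")
    x = 9.0 * c.u / denom
    y = 4.0 * c.v / denom
    return Tristimulus(x / y * Y, Y, (1.0 - x - y) / y * Y)


def _uv(a) -> np.ndarray:
    if isinstance(a, Chromaticity):
        return a.uv
    arr = np.asarray(a, dtype=float)
    return arr[:2]


def uv_distance(a, b) -> float:
    """Euclidean distance in the (u', v') plane; luminance is ignored.

    Accepts :class:`Chromaticity` instances or (u, v) pairs.
    """
    return float(np.hypot(*(_uv(a) - _uv(b))))
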