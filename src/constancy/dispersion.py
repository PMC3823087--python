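"""Central tendency, match variability, and palette-density statistics.

Two measures of the average color match are provided: the arithmetic mean
of the match chromaticities, and the center of the best-fitting ellipse in
the algebraic least-squares sense (the direct constrained conic fit of
Fitzgibbon, Pilu & Fisher, in the numerically stable formulation of Halir &
Flusser; the data are centered and scaled before fitting because the raw
normal equations are badly conditioned at u'v' scale, ~1e-1).

**Variability** is the mean u'v' distance between each match and the
condition's mean match.  **Palette density** counts selectable chips inside
a disc around a reference chromaticity (canonically: center = mean baseline
match, radius = mean baseline variability) and proxies how finely the
response palette samples that region of color space; chips exactly on the
boundary count as inside (a declared rule -- exact ties have measure zero
with measured data, and a fixed convention keeps tests deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .colorimetry import Chromaticity
from .study_data import MatchRecord, Palette

__all__ = [
    "EllipseFit",
    "DispersionResult",
    "DispersionError",
    "mean_chromaticity",
    "fit_ellipse",
    "variability",
    "palette_density",
    "density_sensitivity",
]


class DispersionError(ValueError):
    pass


@dataclass(frozen=True)
class EllipseFit:
    """An ellipse from the direct least-squares conic fit.

    ``semi_axes`` is (a, b) with a >= b > 0; ``orientation`` is the angle
    of the major axis, in radians within [0, pi); ``algebraic_residual`` is
    the sum of squared algebraic distances of the fitted conic at the data,
    in the normalized frame.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    algebraic_residual: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise DispersionError("semi-axes must satisfy a >= b > 0")
        if not all(map(math.isfinite, self.center)):
            raise DispersionError("ellipse center must be finite")


@dataclass(frozen=True)
class DispersionResult:
    cube_name: str
    condition: str
    mean_chrom: Chromaticity
    ellipse_center: tuple[float, float] | None
    variability: float
    n: int

    def __post_init__(self) -> None:
        if self.variability < 0:
            raise DispersionError("variability cannot be negative")


def _points(records: list[MatchRecord], palette: Palette, booth: str) -> np.ndarray:
    if not records:
        raise DispersionError("no records")
    return np.array(
        [palette.chrom(r.chip_id, booth).uv for r in records]
    ).reshape(len(records), 2)


def mean_chromaticity(
    records: list[MatchRecord], palette: Palette, booth: str
) -> Chromaticity:
    """Mean u and v of the chosen chips' chromaticities in ``booth``;
    luminance is discarded."""
    u, v = _points(records, palette, booth).mean(axis=0)
    return Chromaticity(float(u), float(v))


def variability(records: list[MatchRecord], palette: Palette, booth: str) -> float:
    """Mean distance between each match and the mean match."""
    pts = _points(records, palette, booth)
    return float(np.hypot(*(pts - pts.mean(axis=0)).T).mean())


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (ellipse-specific conic constraint).

    Solves the Halir-Flusser partitioned eigenproblem for the conic
    a x^2 + b xy + c y^2 + d x + e y + f = 0 minimizing algebraic distance
    subject to 4ac - b^2 = 1, after centering and isotropically scaling the
    data.  Needs >= 5 points in general position; degenerate configurations
    (collinear points, repeated points) raise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DispersionError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 5:
        raise DispersionError(f"ellipse fit needs >= 5 points, got {n}")

    # normalize: center at centroid, scale mean radius to ~sqrt(2)
    centroid = pts.mean(axis=0)
    scale = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
    if scale == 0:
        raise DispersionError("all points coincide")
    sv = np.linalg.svd(pts - centroid, compute_uv=False)
    if sv[1] <= 1e-9 * sv[0]:
        raise DispersionError("points are collinear; no ellipse is defined")
    xy = (pts - centroid) / scale
    x, y = xy[:, 0], xy[:, 1]

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones(n)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        raise DispersionError("degenerate point configuration") from None
    M = S1 + S2 @ T
    C_inv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
    eigval, eigvec = np.linalg.eig(C_inv @ M)
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(np.isreal(eigval) & (cond > 0))[0]
    if valid.size == 0:
        raise DispersionError("no elliptical solution (degenerate configuration)")
    k = valid[np.argmin(np.abs(eigval[valid]))]
    a1 = np.real(eigvec[:, k])
    coeffs = np.concatenate([a1, T @ a1])  # a, b, c, d, e, f (normalized frame)
    residual = float(((D1 @ a1 + D2 @ (T @ a1)) ** 2).sum())

    A, B, C, D, E, F = coeffs
    den = 4 * A * C - B * B
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    # eigen-decompose the quadratic part for axes and orientation
    Q = np.array([[A, B / 2], [B / 2, C]])
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    w, V = np.linalg.eigh(Q)
    sq_axes = -Fc / w
    if np.any(sq_axes <= 0):
        raise DispersionError("fit did not produce a real ellipse")
    axes = np.sqrt(sq_axes)
    order = np.argsort(axes)[::-1]  # major first
    a_len, b_len = axes[order] * scale
    major = V[:, order[0]]
    theta = math.atan2(major[1], major[0]) % math.pi

    center = (
        float(cx * scale + centroid[0]),
        float(cy * scale + centroid[1]),
    )
    return EllipseFit(
        center=center,
        semi_axes=(float(a_len), float(b_len)),
        orientation=float(theta),
        algebraic_residual=residual,
    )


def palette_density(
    palette: Palette, booth: str, center: Chromaticity, radius: float
) -> int:
    """Number of chips whose ``booth`` chromaticity lies within ``radius``
    of ``center`` (boundary inclusive)."""
    if radius <= 0:
        raise DispersionError("radius must be positive")
    _, arr = palette.uv_array(booth)
    if arr.size == 0:
        return 0
    d = np.hypot(*(arr - np.asarray(center.uv)).T)
    return int((d <= radius).sum())


def density_sensitivity(
    palette: Palette,
    booth: str,
    center: Chromaticity,
    radius: float,
    multipliers,
) -> list[tuple[float, int]]:
    """Palette density at radius x each multiplier, for checking that
    conclusions are stable over a range of disc sizes."""
    ms = [float(m) for m in multipliers]
    if any(m <= 0 for m in ms):
        raise DispersionError("multipliers must be positive")
    return [(m, palette_density(palette, booth, center, radius * m)) for m in ms]
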