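"""Roughness, excess-area and available-surface-area metrics.

The central quantity is the *available surface area* S_A: the true (3D)
area of the below-threshold region of a leveled height field, expressed
as a percent of the projected footprint area. Early microbial
colonization preferentially occupies pattern depressions, so S_A acts as
the fraction of a surface effectively open to attachment: a flat
reference is 100% available by convention, a sinusoid roughly
(1 + excess) × valley fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .heightmap import HeightMap, level_plane

__all__ = [
    "RoughnessReport",
    "AreaReport",
    "roughness",
    "sine_arc_length",
    "triangulated_area",
    "available_surface_area",
    "excess_area",
    "sa_product_estimate",
]


@dataclass
class RoughnessReport:
    """Arithmetic (Ra) and root-mean-square (Rq) roughness in μm."""

    Ra: float
    Rq: float
    n_profiles: int
    field_size: float  # E-W width in μm

    def __post_init__(self) -> None:
        if not (0 <= self.Ra <= self.Rq * (1 + 1e-12)):
            raise ValueError("invariant 0 <= Ra <= Rq violated")


@dataclass
class AreaReport:
    """Footprint vs true 3D area accounting of a height field.

    ``SA_pct`` is the true area of the below-threshold region as a
    percent of the footprint; ``excess_pct`` = 100·(true/footprint − 1).
    """

    footprint_area: float
    true_area: float
    excess_pct: float
    valley_fraction: float
    SA_pct: float
    threshold: float


def roughness(hmap: HeightMap) -> RoughnessReport:
    """Areal Ra = mean|z − z̄| and Rq = rms(z − z̄) after mean leveling."""
    z = hmap.values
    if z.size < 2:
        raise ValueError("need at least 2 pixels")
    d = z - z.mean()
    return RoughnessReport(
        Ra=float(np.abs(d).mean()),
        Rq=float(np.sqrt((d * d).mean())),
        n_profiles=z.shape[0],
        field_size=z.shape[1] * hmap.pixel_size,
    )


def sine_arc_length(A: float, wavelength: float, x1: float, x2: float) -> float:
    """Arc length of ``z = A sin(2πx/λ)`` over ``[x1, x2]`` by quadrature.

    Evaluates ∫ sqrt(1 + (2πA/λ)² cos²(2πx/λ)) dx; always ≥ x2 − x1,
    with equality iff A = 0.
    """
    if x2 <= x1:
        raise ValueError("x2 must exceed x1")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if A == 0:
        return x2 - x1
    k = 2.0 * np.pi / wavelength
    val, _ = quad(
        lambda x: np.sqrt(1.0 + (A * k) ** 2 * np.cos(k * x) ** 2),
        x1,
        x2,
        limit=200,
    )
    return float(val)


def _quad_areas(z: np.ndarray, px: float) -> np.ndarray:
    """True 3D area of each pixel quad, split into two triangles.

    Quad (i, j) has corners z[i, j], z[i, j+1], z[i+1, j], z[i+1, j+1];
    triangles are (00, 10, 01) and (10, 11, 01).
    """
    z00 = z[:-1, :-1]
    z10 = z[1:, :-1]
    z01 = z[:-1, 1:]
    z11 = z[1:, 1:]

    def tri(za, zb, zc, va, vb, vc):
        ux, uy, uz = (vb[0] - va[0]) * px, (vb[1] - va[1]) * px, zb - za
        wx, wy, wz = (vc[0] - va[0]) * px, (vc[1] - va[1]) * px, zc - za
        cx = uy * wz - uz * wy
        cy = uz * wx - ux * wz
        cz = ux * wy - uy * wx
        return 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)

    # offsets (dx_east, dy_south) in pixel units
    a1 = tri(z00, z10, z01, (0, 0), (0, 1), (1, 0))
    a2 = tri(z10, z11, z01, (0, 1), (1, 1), (1, 0))
    return a1 + a2


def triangulated_area(hmap: HeightMap) -> float:
    """Total true 3D area (μm²) over the (rows−1)×(cols−1) quad grid."""
    return float(_quad_areas(hmap.values, hmap.pixel_size).sum())


def available_surface_area(
    hmap: HeightMap,
    threshold: float = 0.0,
    level: bool = True,
    flat_eps: float = 0.05,
) -> AreaReport:
    """Available surface area S_A of the below-threshold region.

    The map is plane-leveled (unless ``level=False``), each pixel quad is
    triangulated on the height field, and quads whose center height lies
    below ``threshold`` form the "valley" region. S_A is the true area
    of that region per unit footprint, in percent.

    A surface flatter than ``flat_eps`` (Rq, default 0.05 μm) is treated
    as the flat reference: S_A = 100% and valley_fraction = 1, since the
    entire footprint is available rather than none of it. The default
    sits between the residual roughness of a flat elastomer replica
    (Rq ≈ 0.03 μm) and the shallowest patterned surfaces (Rq ≈ 0.1 μm).
    """
    z = level_plane(hmap.values) if level else hmap.values
    px = hmap.pixel_size
    areas = _quad_areas(z, px)
    nq = areas.size
    if nq == 0:
        raise ValueError("map too small to triangulate")
    footprint = nq * px * px
    true_area = float(areas.sum())
    excess_pct = 100.0 * (true_area / footprint - 1.0)

    if float(np.sqrt(((z - z.mean()) ** 2).mean())) < flat_eps:
        return AreaReport(footprint, true_area, excess_pct, 1.0, 100.0, threshold)

    zc = (z[:-1, :-1] + z[1:, :-1] + z[:-1, 1:] + z[1:, 1:]) / 4.0
    below = zc < threshold
    valley_fraction = float(below.mean())
    if not below.any():
        warnings.warn("no region below threshold: S_A = 0", stacklevel=2)
        return AreaReport(footprint, true_area, excess_pct, 0.0, 0.0, threshold)
    sa_pct = 100.0 * float(areas[below].sum()) / footprint
    return AreaReport(footprint, true_area, excess_pct, valley_fraction, sa_pct, threshold)


def excess_area(hmap: HeightMap, level: bool = True) -> float:
    """Percent by which true 3D area exceeds the projected footprint."""
    z = level_plane(hmap.values) if level else hmap.values
    areas = _quad_areas(z, hmap.pixel_size)
    footprint = areas.size * hmap.pixel_size**2
    return 100.0 * (float(areas.sum()) / footprint - 1.0)


def sa_product_estimate(excess_pct: float, valley_fraction: float) -> float:
    """Product estimator of S_A: (1 + excess/100) × valley fraction, in %.

    This is the back-of-envelope decomposition (total relative area ×
    fraction of it lying in depressions); e.g. a 10% excess with half
    the footprint in valleys gives 1.10 × 0.50 = 55%. It coincides with
    :func:`available_surface_area` only when relative area is
    distributed evenly between hills and valleys (symmetric profiles).
    """
    if not (0.0 <= valley_fraction <= 1.0):
        raise ValueError("valley_fraction must lie in [0, 1]")
    return (1.0 + excess_pct / 100.0) * valley_fraction * 100.0
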