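"""Height-map container and shared geometric conventions.

A :class:`HeightMap` is the universal currency between the synthesis,
metrics, simulation and analysis stages: a regular square-pixel grid of
surface heights in micrometers.

Coordinate and angle conventions used throughout the package:

* array row 0 is the north edge, column 0 the west edge;
* physical ``x`` runs east (columns), ``y`` runs south (rows), both in μm;
* in-plane directions are reported as axial angles in degrees measured
  from the N–S (vertical) axis, normalized to ``[-90, 90)``; a line at
  angle ``alpha`` has direction vector ``(sin(alpha), -cos(alpha))`` in
  ``(x_east, y_south)`` components, so 0° is N–S and ±90° is E–W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeightMap",
    "axial_deg",
    "axial_diff_deg",
    "direction_vector",
    "level_plane",
]


def axial_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Normalize an angle (degrees) to the axial range ``[-90, 90)``.

    Lines are 180°-periodic, so 95° and -85° describe the same axis.
    """
    out = (np.asarray(angle, dtype=float) + 90.0) % 180.0 - 90.0
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


def axial_diff_deg(a: float, b: float) -> float:
    """Smallest absolute difference between two axial angles, in [0, 90]."""
    d = abs(axial_deg(a - b))
    return min(d, 180.0 - d) if d > 90.0 else d


def direction_vector(angle_deg: float) -> tuple[float, float]:
    """Unit direction ``(dx_east, dy_south)`` of a line at ``angle_deg``."""
    a = math.radians(angle_deg)
    return math.sin(a), -math.cos(a)


def level_plane(values: np.ndarray) -> np.ndarray:
    """Subtract the degree-1 least-squares plane from a height grid."""
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    r = np.arange(rows, dtype=float) - (rows - 1) / 2.0
    c = np.arange(cols, dtype=float) - (cols - 1) / 2.0
    R, C = np.meshgrid(r, c, indexing="ij")
    # orthogonal centered basis -> closed-form coefficients
    mean = values.mean()
    sr = (values * R).sum() / (R * R).sum() if rows > 1 else 0.0
    sc = (values * C).sum() / (C * C).sum() if cols > 1 else 0.0
    return values - mean - sr * R - sc * C


@dataclass
class HeightMap:
    """Regular-grid scalar surface in μm with square pixels.

    Parameters
    ----------
    values
        2D array of heights (μm), shape ``(rows, cols)``; row 0 = north.
    pixel_size
        Pixel pitch in μm/pixel (square pixels).
    """

    values: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("height map must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def size_um(self) -> tuple[float, float]:
        """Physical extent (height_NS, width_EW) in μm."""
        r, c = self.values.shape
        return r * self.pixel_size, c * self.pixel_size

    @property
    def footprint_area(self) -> float:
        """Projected (2D) area of the full grid in μm²."""
        r, c = self.values.shape
        return r * c * self.pixel_size**2

    def leveled(self, plane: bool = False) -> "HeightMap":
        """Return a copy with zero mean (optionally plane-fit leveled)."""
        v = level_plane(self.values) if plane else self.values - self.values.mean()
        return HeightMap(v, self.pixel_size, dict(self.meta))

    def value_at(self, x_um: float, y_um: float) -> float:
        """Height at physical position (bilinear interpolation)."""
        r = y_um / self.pixel_size - 0.5
        c = x_um / self.pixel_size - 0.5
        rows, cols = self.values.shape
        r = min(max(r, 0.0), rows - 1.0)
        c = min(max(c, 0.0), cols - 1.0)
        r0, c0 = int(r), int(c)
        r1, c1 = min(r0 + 1, rows - 1), min(c0 + 1, cols - 1)
        fr, fc = r - r0, c - c0
        v = self.values
        return float(
            v[r0, c0] * (1 - fr) * (1 - fc)
            + v[r1, c0] * fr * (1 - fc)
            + v[r0, c1] * (1 - fr) * fc
            + v[r1, c1] * fr * fc
        )

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids ``(X_east, Y_south)`` in μm."""
        rows, cols = self.values.shape
        x = (np.arange(cols) + 0.5) * self.pixel_size
        y = (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)
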