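"""Synthetic microbial colonization of wrinkled surfaces.

Stands in for scan data: places model microbes on height maps with the
statistical structure the downstream analysis assumes, and renders
scan-like images. The adhesion model is a sequential random adsorption
scheme with three interpretable knobs:

* ``valley_affinity`` — multiplicative acceptance odds for candidate
  positions below the threshold plane (cells settle into depressions);
* ``guidance_strength`` — von Mises concentration of the cell long axis
  about the local groove direction (contact guidance);
* ``rate_per_SA`` + per-pattern ``lag_hours`` — areal coverage grows
  linearly in time, proportional to the available surface-area
  fraction, after a pattern-dependent onset delay (tortuous biaxial
  patterns frustrate early proliferation).

Strain morphologies (cross-section a, length b, with SDs) follow
electron-microscopy estimates for S. aureus, P. aeruginosa, E. coli K12
and C. albicans; valley-confined cells adopt the deformed dimensions
measured on uniaxial wrinkles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .heightmap import HeightMap, axial_deg

__all__ = [
    "CellSpec",
    "STRAINS",
    "CellPlacement",
    "ColonizationModel",
    "ColonySnapshot",
    "sample_cell",
    "local_groove_direction",
    "place_cells",
    "coverage_trajectory",
    "simulate_coverage_dataset",
    "render_afm",
]


@dataclass(frozen=True)
class CellSpec:
    """Strain morphology: cross-section ``a`` and length ``b`` in μm.

    ``confined_a``/``confined_b`` are the deformed dimensions adopted
    when a cell is squeezed into a uniaxial wrinkle valley narrower than
    its relaxed cross-section.
    """

    strain_name: str
    shape: str  # "spheroid" | "rod"
    a_mean: float
    a_sd: float
    b_mean: float
    b_sd: float
    gram: str  # "+" | "-"
    confined_a: float
    confined_b: float

    def __post_init__(self) -> None:
        if self.shape not in ("spheroid", "rod"):
            raise ValueError("shape must be 'spheroid' or 'rod'")
        if min(self.a_mean, self.b_mean, self.confined_a, self.confined_b) <= 0:
            raise ValueError("dimensions must be positive")
        if self.a_mean > self.b_mean:
            raise ValueError("cross-section a_mean must not exceed length b_mean")

    @property
    def aspect_ratio(self) -> float:
        return self.b_mean / self.a_mean


#: Morphometrics of the four model strains (means ± SD in μm).
STRAINS: dict[str, CellSpec] = {
    "S. aureus": CellSpec("S. aureus", "spheroid", 0.8, 0.3, 0.9, 0.3, "+", 0.9, 0.8),
    "P. aeruginosa": CellSpec("P. aeruginosa", "rod", 0.7, 0.2, 1.7, 0.2, "-", 0.7, 2.5),
    "E. coli K12": CellSpec("E. coli K12", "rod", 0.6, 0.2, 1.9, 0.2, "-", 0.8, 1.7),
    "C. albicans": CellSpec("C. albicans", "spheroid", 3.8, 1.5, 4.1, 1.5, "+", 3.9, 4.2),
}


@dataclass
class CellPlacement:
    """A placed cell: center (μm), axial angle from N–S, realized axes."""

    center: tuple[float, float]
    angle: float
    a_eff: float
    b_eff: float
    height_offset: float = 0.0
    in_valley: bool = False

    def __post_init__(self) -> None:
        if self.a_eff > self.b_eff * (1 + 1e-12):
            raise ValueError("a_eff must not exceed b_eff")

    @property
    def area(self) -> float:
        """Footprint ellipse area π·(a/2)(b/2) in μm²."""
        return math.pi * self.a_eff * self.b_eff / 4.0


@dataclass
class ColonizationModel:
    """Knobs of the colonization process (see module docstring)."""

    valley_affinity: float = 5.0
    guidance_strength: float = 6.0
    rate_per_SA: float = 5.0  # coverage-% per hour per unit SA fraction
    lag_hours: dict[str, float] = field(
        default_factory=lambda: {"F": 0.0, "1D": 0.0, "C": 2.0, "H": 2.0}
    )
    jamming_ceiling: float = 55.0  # sequential ellipse adsorption saturates near here
    seed: int = 0

    def __post_init__(self) -> None:
        if self.valley_affinity < 1.0:
            raise ValueError("valley_affinity must be >= 1")
        if self.guidance_strength < 0 or self.rate_per_SA < 0:
            raise ValueError("guidance_strength and rate_per_SA must be >= 0")
        if any(v < 0 for v in self.lag_hours.values()):
            raise ValueError("lags must be >= 0")


@dataclass
class ColonySnapshot:
    """Placements on a surface at one incubation time."""

    time_h: float
    placements: list[CellPlacement]
    surface: HeightMap
    strain: CellSpec

    def coverage_pct(self) -> float:
        return 100.0 * sum(p.area for p in self.placements) / self.surface.footprint_area

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": [p.center[0] for p in self.placements],
                "y_um": [p.center[1] for p in self.placements],
                "angle_deg": [p.angle for p in self.placements],
                "a_eff_um": [p.a_eff for p in self.placements],
                "b_eff_um": [p.b_eff for p in self.placements],
                "in_valley": [p.in_valley for p in self.placements],
            }
        )


def sample_cell(spec: CellSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Draw realized (a_eff, b_eff) from truncated normals.

    Truncation at 0.2× the mean guards against nonphysical near-zero
    draws. Rods resample until b_eff >= a_eff; spheroids (a ≈ b) swap
    the pair instead, to avoid biasing their nearly equal means.
    """

    def draw(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        lo = 0.2 * mean
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if v >= lo:
                return v
        return lo

    for _ in range(1000):
        a = draw(spec.a_mean, spec.a_sd)
        b = draw(spec.b_mean, spec.b_sd)
        if b >= a:
            return a, b
        if spec.shape == "spheroid":
            return b, a
    return min(a, b), max(a, b)


def local_groove_direction(
    hmap: HeightMap,
    point: tuple[float, float],
    window_um: float = 2.0,
    coherence_tol: float = 0.2,
) -> float | None:
    """Groove (minimal height variation) direction at a point, degrees.

    Uses the structure tensor of the height gradient over a window of
    about one pattern wavelength. Returns the axial angle from the N–S
    axis in [-90, 90), or ``None`` when the window is isotropic (flat or
    unpatterned) within ``coherence_tol``.
    """
    px = hmap.pixel_size
    rows, cols = hmap.shape
    c = int(round(point[0] / px - 0.5))
    r = int(round(point[1] / px - 0.5))
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError("point outside field")
    half = max(2, int(round(window_um / (2 * px))))
    r0, r1 = max(0, r - half), min(rows, r + half + 1)
    c0, c1 = max(0, c - half), min(cols, c + half + 1)
    patch = hmap.values[r0:r1, c0:c1]
    gy, gx = np.gradient(patch, px)  # gy along south, gx along east
    jxx = float((gx * gx).mean())
    jyy = float((gy * gy).mean())
    jxy = float((gx * gy).mean())
    trace = jxx + jyy
    if trace < 1e-12:
        return None
    coherence = math.hypot(jxx - jyy, 2 * jxy) / trace
    if coherence < coherence_tol:
        return None
    # dominant gradient direction (double-angle form), from the x-axis
    phi = 0.5 * math.atan2(2 * jxy, jxx - jyy)
    # groove axis is perpendicular to the gradient; with our N-S
    # convention that works out to the gradient angle itself re-based
    return axial_deg(math.degrees(phi))


class _EllipseField:
    """Overlap bookkeeping for sequential ellipse adsorption."""

    def __init__(self, bin_size: float) -> None:
        self.bin = max(bin_size, 1e-6)
        self.grid: dict[tuple[int, int], list[CellPlacement]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return int(x // self.bin), int(y // self.bin)

    def neighbors(self, x: float, y: float) -> list[CellPlacement]:
        kx, ky = self._key(x, y)
        out: list[CellPlacement] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                out.extend(self.grid.get((kx + dx, ky + dy), ()))
        return out

    def add(self, p: CellPlacement) -> None:
        self.grid.setdefault(self._key(*p.center), []).append(p)


def _point_in_ellipse(x: float, y: float, p: CellPlacement) -> bool:
    dx, dy = x - p.center[0], y - p.center[1]
    # major axis direction (sin a, -cos a) in (east, south)
    s, c = math.sin(math.radians(p.angle)), -math.cos(math.radians(p.angle))
    u = dx * s + dy * c
    v = -dx * c + dy * s
    return (u / (p.b_eff / 2)) ** 2 + (v / (p.a_eff / 2)) ** 2 < 1.0


def _ellipses_overlap(p: CellPlacement, q: CellPlacement, n_probe: int = 24) -> bool:
    d = math.hypot(p.center[0] - q.center[0], p.center[1] - q.center[1])
    if d >= (p.b_eff + q.b_eff) / 2:
        return False
    if d < (p.a_eff + q.a_eff) / 2:
        return True
    # probe boundary points of each ellipse against the other
    for a, b in ((p, q), (q, p)):
        if _point_in_ellipse(a.center[0], a.center[1], b):
            return True
        s, c = math.sin(math.radians(a.angle)), -math.cos(math.radians(a.angle))
        for t in np.linspace(0, 2 * math.pi, n_probe, endpoint=False):
            u = math.cos(t) * a.b_eff / 2
            v = math.sin(t) * a.a_eff / 2
            x = a.center[0] + u * s - v * c
            y = a.center[1] + u * c + v * s
            if _point_in_ellipse(x, y, b):
                return True
    return False


def place_cells(
    hmap: HeightMap,
    spec: CellSpec,
    model: ColonizationModel,
    target_coverage_pct: float,
    rng: np.random.Generator,
    threshold: float = 0.0,
    valley_width_um: float | None = None,
    groove_window_um: float = 2.0,
    max_attempts: int | None = None,
) -> list[CellPlacement]:
    """Sequential random adsorption of cells up to a target coverage.

    Candidate centers are uniform over the field; candidates on hills
    (center height >= ``threshold``) are accepted with odds reduced by
    ``model.valley_affinity``. The cell long axis is drawn von Mises
    around the local groove direction (uniform where the surface is
    isotropic or guidance is 0). When ``valley_width_um`` is given, a
    valley-resident cell whose relaxed cross-section exceeds that width
    adopts the strain's confined dimensions. Overlapping candidates are
    rejected; placement stops at the target coverage or when the
    attempt budget is exhausted (with a warning).
    """
    if not (0.0 <= target_coverage_pct <= 60.0):
        raise ValueError("target coverage must lie in [0, 60] %")
    h_ns, w_ew = hmap.size_um
    field_area = hmap.footprint_area
    target_area = target_coverage_pct / 100.0 * field_area
    placements: list[CellPlacement] = []
    if target_area <= 0:
        return placements
    grid = _EllipseField(bin_size=2.0 * spec.b_mean + 4.0 * spec.b_sd)
    placed_area = 0.0
    expected_n = max(1, int(target_area / (math.pi * spec.a_mean * spec.b_mean / 4)))
    budget = max_attempts if max_attempts is not None else 300 * expected_n + 2000
    inv_aff = 1.0 / model.valley_affinity if np.isfinite(model.valley_affinity) else 0.0

    for _ in range(budget):
        a_eff, b_eff = sample_cell(spec, rng)
        # keep the whole footprint inside the field so areal coverage is
        # exactly the sum of ellipse areas over the footprint
        margin = min(b_eff / 2.0, w_ew / 4.0, h_ns / 4.0)
        x = rng.uniform(margin, w_ew - margin)
        y = rng.uniform(margin, h_ns - margin)
        z = hmap.value_at(x, y)
        in_valley = z < threshold
        if not in_valley and rng.random() >= inv_aff:
            continue
        groove = local_groove_direction(hmap, (x, y), window_um=groove_window_um)
        if groove is None or model.guidance_strength == 0:
            angle = rng.uniform(-90.0, 90.0)
        else:
            # axial von Mises: concentrate the doubled angle
            dev = rng.vonmises(0.0, model.guidance_strength)
            angle = axial_deg(groove + math.degrees(dev) / 2.0)
        if (
            valley_width_um is not None
            and in_valley
            and a_eff > valley_width_um
        ):
            a_eff, b_eff = spec.confined_a, spec.confined_b
            if a_eff > b_eff:
                a_eff, b_eff = b_eff, a_eff
        cand = CellPlacement((x, y), angle, a_eff, b_eff, height_offset=z, in_valley=in_valley)
        if any(_ellipses_overlap(cand, other) for other in grid.neighbors(x, y)):
            continue
        placements.append(cand)
        grid.add(cand)
        placed_area += cand.area
        if placed_area >= target_area:
            break
    else:
        warnings.warn(
            f"attempt budget exhausted at {100 * placed_area / field_area:.2f}% "
            f"of target {target_coverage_pct:.2f}%",
            stacklevel=2,
        )
    return placements


def coverage_trajectory(
    model: ColonizationModel,
    SA_fraction: float,
    pattern: str,
    times_h,
) -> np.ndarray:
    """Deterministic coverage law: rate·SA·max(0, t − lag), capped.

    Coverage (%) grows linearly in time after the pattern's onset lag,
    at a rate proportional to the available surface-area fraction, up
    to the jamming ceiling of monolayer ellipse packing.
    """
    if not (0.0 < SA_fraction <= 1.1):
        raise ValueError("SA_fraction must lie in (0, 1.1]")
    if pattern not in model.lag_hours:
        raise ValueError(f"unknown pattern {pattern!r}; lags defined for {sorted(model.lag_hours)}")
    t = np.asarray(times_h, dtype=float)
    lag = model.lag_hours[pattern]
    cov = model.rate_per_SA * SA_fraction * np.clip(t - lag, 0.0, None)
    return np.minimum(cov, model.jamming_ceiling)


def simulate_coverage_dataset(
    model: ColonizationModel,
    sa_fractions: dict[str, float],
    times_h=(0.0, 2.0, 4.0, 6.0),
    replicates: int = 3,
    noise_rel: float = 0.01,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicated coverage measurements from the linear-lag law.

    Gaussian measurement noise with sd = ``noise_rel`` × the true
    coverage is added independently per (pattern, time, replicate);
    coverage is floored at 0.
    """
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    recs = []
    for pattern, sa in sa_fractions.items():
        truth = coverage_trajectory(model, sa, pattern, times_h)
        for rep in range(replicates):
            noisy = truth + rng.normal(0.0, noise_rel * np.abs(truth))
            for t, c in zip(times_h, np.clip(noisy, 0.0, None)):
                recs.append(
                    {
                        "pattern": pattern,
                        "SA_pct": 100.0 * sa,
                        "time_h": float(t),
                        "coverage_pct": float(c),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame.from_records(recs)


def render_afm(
    hmap: HeightMap,
    placements: list[CellPlacement],
    tip_radius: float = 0.0,
    noise_rms: float = 0.0,
    rng: np.random.Generator | None = None,
) -> HeightMap:
    """Render placed cells onto a surface as a scan-like height image.

    Each cell is a half-ellipsoidal cap of height a_eff/2, max-composited
    onto the substrate. The cap base rests at the highest surface point
    along the cell's long axis — the rigid-body contact line — so a rod
    lying along a groove sinks to the valley floor while one bridging a
    pit rests on the rims. ``tip_radius`` applies a morphological
    dilation by a spherical tip (the classic tip-convolution artifact);
    ``noise_rms`` adds Gaussian height noise.
    """
    z = hmap.values.copy()
    px = hmap.pixel_size
    rows, cols = z.shape
    for p in placements:
        s_ax, c_ax = math.sin(math.radians(p.angle)), -math.cos(math.radians(p.angle))
        ts = np.linspace(-p.b_eff / 2.0, p.b_eff / 2.0, 9)
        base = max(
            hmap.value_at(p.center[0] + t * s_ax, p.center[1] + t * c_ax) for t in ts
        )
        rb = p.b_eff / 2.0
        ra = p.a_eff / 2.0
        h = p.a_eff / 2.0
        # bounding box in pixels
        ext = rb + px
        c0 = max(0, int((p.center[0] - ext) / px - 0.5))
        c1 = min(cols, int((p.center[0] + ext) / px + 1.5))
        r0 = max(0, int((p.center[1] - ext) / px - 0.5))
        r1 = min(rows, int((p.center[1] + ext) / px + 1.5))
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * px - p.center[0]
        ys = (np.arange(r0, r1) + 0.5) * px - p.center[1]
        X, Y = np.meshgrid(xs, ys)
        s, c = math.sin(math.radians(p.angle)), -math.cos(math.radians(p.angle))
        U = X * s + Y * c
        V = -X * c + Y * s
        q = 1.0 - (U / rb) ** 2 - (V / ra) ** 2
        cap = base + h * np.sqrt(np.clip(q, 0.0, None))
        mask = q > 0
        region = z[r0:r1, c0:c1]
        region[mask] = np.maximum(region[mask], cap[mask])
    if tip_radius > 0:
        from scipy import ndimage

        n = int(math.ceil(tip_radius / px))
        xs = np.arange(-n, n + 1) * px
        X, Y = np.meshgrid(xs, xs)
        r2 = X * X + Y * Y
        inside = r2 <= tip_radius**2
        tip = np.full_like(r2, -np.inf)
        tip[inside] = np.sqrt(tip_radius**2 - r2[inside]) - tip_radius
        z = ndimage.grey_dilation(z, structure=tip)
    if noise_rms > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        z = z + rng.normal(0.0, noise_rms, size=z.shape)
    return HeightMap(z, px, dict(hmap.meta))
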