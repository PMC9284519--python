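"""Measurement stage: background subtraction, segmentation, orientation
distributions, areal coverage and line-profile morphometrics.

The pipeline mirrors a scanning-probe workflow: the periodic substrate
pattern is subtracted from the height image, cells are isolated by a
height threshold and connected-component labeling with moment-based
ellipse descriptors, and orientation statistics are built either from
local 2D-FFT azimuthal averages over subimages (the primary method) or
directly from the fitted ellipse angles (an independent cross-check).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import measure, morphology

from .heightmap import HeightMap, axial_deg, direction_vector, level_plane

__all__ = [
    "ObjectMeasure",
    "SegmentationResult",
    "OrientationDistribution",
    "CoverageResult",
    "subtract_background",
    "segment_cells",
    "orientation_distribution",
    "ellipse_angle_distribution",
    "areal_coverage",
    "profile_morphometrics",
]


@dataclass
class ObjectMeasure:
    """One segmented cell: geometry in physical units."""

    centroid: tuple[float, float]  # (x_east, y_south) μm
    area: float  # thresholded footprint, μm²
    area_full: float  # cap-corrected full footprint, μm²
    major: float  # μm
    minor: float  # μm
    angle: float  # axial degrees from N-S
    max_height: float  # μm above corrected background


@dataclass
class SegmentationResult:
    label_map: np.ndarray
    objects: list[ObjectMeasure]
    threshold_used: float
    pixel_size: float

    @property
    def n_objects(self) -> int:
        return len(self.objects)


@dataclass
class OrientationDistribution:
    """Binned angular density over a declared window, unit sum."""

    bin_centers: np.ndarray
    density: np.ndarray
    window: tuple[float, float]
    n_cells: int
    n_subimages: int

    def modal_angle(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.density))])

    def circular_variance(self) -> float:
        """Axial circular variance 1 − |Σ p·exp(2iθ)| of the density."""
        th = np.radians(self.bin_centers * 2.0)
        c = (self.density * np.exp(1j * th)).sum()
        return float(1.0 - abs(c))


@dataclass
class CoverageResult:
    coverage_pct: float
    field_area: float
    n_fields: int
    per_field: list[float]
    mean: float
    sd: float


def _parse_window(window) -> tuple[float, float]:
    if isinstance(window, str):
        known = {"0-90": (0.0, 90.0), "-45-45": (-45.0, 45.0)}
        if window not in known:
            raise ValueError(f"unknown window {window!r}; use {sorted(known)} or a (lo, hi) pair")
        return known[window]
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window high edge must exceed low edge")
    return lo, hi


def _into_window(angles: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map axial angles into [lo, hi]; out-of-window angles become NaN."""
    a = np.asarray(angles, dtype=float).copy()
    a = np.where(a < lo, a + 180.0, a)
    a = np.where(a > hi, a - 180.0, a)
    a[(a < lo) | (a > hi)] = np.nan
    return a


def _detect_pattern_peaks(
    leveled: np.ndarray,
    px: float,
    f0: float,
    band: tuple[float, float],
    max_peaks: int,
    rel_strength: float,
) -> list[tuple[float, float]]:
    """Dominant narrow spectral peaks (fy, fx in cycles/μm) of a field.

    Detection runs on the Hann-windowed spectrum (low leakage); each
    peak frequency is refined to sub-bin accuracy by log-parabolic
    interpolation, so off-grid pattern periods are captured exactly.
    Only one half-plane is returned (conjugates are implicit).
    """
    rows, cols = leveled.shape
    win = np.outer(np.hanning(rows), np.hanning(cols))
    mag = np.abs(np.fft.fft2(leveled * win))
    fy = np.fft.fftfreq(rows, d=px)
    fx = np.fft.fftfreq(cols, d=px)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    R = np.hypot(FX, FY)
    half = (FY < 0) | ((FY == 0) & (FX > 0))
    cand = (R >= band[0] * f0) & (R <= band[1] * f0) & half
    if not cand.any() or mag[cand].max() <= 0:
        return []
    local_max = mag >= ndimage.maximum_filter(mag, size=3, mode="wrap")
    sel = cand & local_max & (mag > rel_strength * mag[cand].max())
    idx = np.argwhere(sel)
    idx = idx[np.argsort(mag[sel])[::-1][:max_peaks]]

    def sub_bin(c: float, lo: float, hi: float) -> float:
        c, lo, hi = (math.log(v + 1e-300) for v in (c, lo, hi))
        d = lo - 2 * c + hi
        return 0.5 * (lo - hi) / d if d < 0 else 0.0

    dfy, dfx = fy[1] - fy[0], fx[1] - fx[0]
    freqs = []
    for i, j in idx:
        si = sub_bin(mag[i, j], mag[(i - 1) % rows, j], mag[(i + 1) % rows, j])
        sj = sub_bin(mag[i, j], mag[i, (j - 1) % cols], mag[i, (j + 1) % cols])
        freqs.append((fy[i] + si * dfy, fx[j] + sj * dfx))
    return freqs


def subtract_background(
    image: HeightMap,
    pattern_wavelength: float,
    method: str = "fit",
    stripe_period: float | None = None,
    max_peaks: int = 12,
    rel_strength: float = 0.05,
    harmonic_band: tuple[float, float] = (0.5, 3.5),
    n_iter: int = 3,
) -> HeightMap:
    """Remove the periodic substrate pattern from a height image.

    The default estimator exploits the spectral structure of the
    problem: a wrinkle pattern concentrates its energy in a handful of
    narrow Fourier peaks around the pattern fundamental and harmonics,
    while cells are sparse, broadband objects. Peak frequencies inside
    ``harmonic_band``/λ are detected on a Hann-windowed spectrum and
    refined to sub-bin accuracy; sinusoids at those exact frequencies
    are then fitted to the plane-leveled image by iteratively masked
    least squares, where pixels with large positive residuals (cells)
    are excluded from the fit. Pattern under the cells is therefore
    extrapolated from the cell-free surround, a flat image yields
    near-zero coefficients (cells pass through unchanged), and the
    operation is idempotent.

    For chevron patterns whose kink stripes modulate the phase,
    ``stripe_period`` (= twice the arm length) adds the sub-resolution
    sideband ladder along the stripe axis to the fitting basis.

    ``method="opening"`` instead estimates the background by grayscale
    morphological opening with a flat disk of diameter 1.5λ, which
    removes any feature narrower than the disk — appropriate for
    near-flat substrates, but it flattens the pattern itself on
    wrinkled ones.
    """
    rows, cols = image.shape
    px = image.pixel_size
    if pattern_wavelength >= min(rows, cols) * px:
        raise ValueError("pattern wavelength must be smaller than the field")
    if pattern_wavelength < 4 * px:
        raise ValueError("pattern wavelength not resolvable (< 4 px)")
    leveled = level_plane(image.values)

    if method == "opening":
        radius_px = max(1, int(round(0.75 * pattern_wavelength / px)))
        footprint = morphology.disk(radius_px)
        bg = ndimage.grey_opening(leveled, footprint=footprint)
        return HeightMap(leveled - bg, px, dict(image.meta))
    if method != "fit":
        raise ValueError(f"unknown method {method!r}")

    f0 = 1.0 / pattern_wavelength
    freqs = _detect_pattern_peaks(
        leveled, px, f0, harmonic_band, max_peaks, rel_strength
    )
    if not freqs:
        return HeightMap(leveled, px, dict(image.meta))
    if stripe_period is not None and len(freqs) >= 2:
        # ladder axis from the two strongest peaks (arm pair); fold the
        # half-plane sign ambiguity by taking the shorter difference
        d1 = np.array(freqs[0]) - np.array(freqs[1])
        d2 = np.array(freqs[0]) + np.array(freqs[1])
        d = d1 if np.hypot(*d1) < np.hypot(*d2) else d2
        norm = float(np.hypot(*d))
        if norm > 1e-9:
            qy, qx = d / norm
            base = list(freqs[: max(4, max_peaks // 2)])
            for fyy, fxx in base:
                for m in range(-4, 5):
                    if m:
                        freqs.append(
                            (fyy + m * qy / stripe_period, fxx + m * qx / stripe_period)
                        )
    # deduplicate near-coincident frequencies
    uniq: list[tuple[float, float]] = []
    for f in freqs:
        if all(math.hypot(f[0] - g[0], f[1] - g[1]) > 1e-4 for g in uniq):
            uniq.append(f)

    x = (np.arange(cols) + 0.5) * px
    y = (np.arange(rows) + 0.5) * px
    X, Y = np.meshgrid(x, y)
    columns = [np.ones_like(X)]
    for fyy, fxx in uniq:
        phase = 2.0 * np.pi * (fxx * X + fyy * Y)
        columns.append(np.sin(phase))
        columns.append(np.cos(phase))
    A = np.stack([c.ravel() for c in columns], axis=1)
    b = leveled.ravel()
    mask = np.ones(b.size, dtype=bool)
    coef = np.zeros(A.shape[1])
    for _ in range(n_iter):
        Am = A[mask]
        gram = Am.T @ Am
        gram.flat[:: gram.shape[0] + 1] += 1e-9 * max(np.trace(gram), 1.0)
        coef = np.linalg.solve(gram, Am.T @ b[mask])
        resid = b - A @ coef
        med = float(np.median(resid[mask]))
        scale = 1.4826 * float(np.median(np.abs(resid[mask] - med)))
        new_mask = resid < med + 2.5 * max(scale, 1e-6)
        if new_mask.sum() < 0.2 * b.size or (new_mask == mask).all():
            break
        mask = new_mask
    background = (A @ coef).reshape(rows, cols)
    return HeightMap(leveled - background, px, dict(image.meta))


def segment_cells(
    corrected: HeightMap,
    height_threshold: float = 0.15,
    min_area: float = 0.2,
) -> SegmentationResult:
    """Threshold + connected components + moment-based ellipse fit.

    ``height_threshold`` (μm above the corrected background) separates
    cells from residual pattern; components smaller than ``min_area``
    (μm²) are removed and labels are renumbered contiguously from 1.
    Each object also carries ``area_full``, the footprint extrapolated
    to the cell base assuming an ellipsoidal-cap height profile
    (a threshold at height t on a cap of peak height h keeps only the
    fraction 1 − (t/h)² of the footprint).
    """
    z = corrected.values
    px = corrected.pixel_size
    mask = z > height_threshold
    labels = measure.label(mask, connectivity=2)
    objs: list[ObjectMeasure] = []
    keep: list[int] = []
    for prop in measure.regionprops(labels, intensity_image=z):
        area_um2 = prop.area * px * px
        if area_um2 < min_area:
            continue
        keep.append(prop.label)
        r0, c0 = prop.centroid
        hmax = float(prop.intensity_max)
        # marginal slivers (peak barely above threshold) are fragments,
        # not caps: extrapolating them would blow their area up
        if hmax > 1.4 * height_threshold:
            frac = 1.0 - (height_threshold / hmax) ** 2
        else:
            frac = 1.0
        objs.append(
            ObjectMeasure(
                centroid=((c0 + 0.5) * px, (r0 + 0.5) * px),
                area=area_um2,
                area_full=area_um2 / frac,
                major=prop.axis_major_length * px,
                minor=prop.axis_minor_length * px,
                angle=axial_deg(-math.degrees(prop.orientation)),
                max_height=hmax,
            )
        )
    relabeled = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        relabeled[labels == old] = new
    return SegmentationResult(relabeled, objs, height_threshold, px)


def _iter_subimages(mask: np.ndarray, size: int, overlap: float = 0.5):
    rows, cols = mask.shape
    size = min(size, rows, cols)
    step = max(1, int(size * (1.0 - overlap)))
    for r0 in range(0, rows - size + 1, step):
        for c0 in range(0, cols - size + 1, step):
            yield mask[r0 : r0 + size, c0 : c0 + size]


def orientation_distribution(
    seg: SegmentationResult,
    window="0-90",
    subimage_px: int = 64,
    bin_deg: float = 5.0,
    radial_band: tuple[float, float] | None = None,
    mode: str = "averaged",
) -> OrientationDistribution:
    """Cell orientation density from local FFT azimuthal averages.

    The binary object mask is divided into Hann-windowed subimages
    (50% overlap); each power spectrum is integrated azimuthally over
    the radial band ``radial_band`` in cycles/μm (default
    ``[1/(2 b_med), 1/a_med]`` from the median fitted cell axes, which
    suppresses residual pattern harmonics and windowing leakage).
    Spectral angles are rotated by 90° so that reported angles are
    real-space cell orientations: an elongated object concentrates
    spectral power perpendicular to its long axis. Subimage
    distributions are averaged (``mode="averaged"``) or pooled
    (``mode="pooled"``) and normalized to unit sum over the window.
    """
    if seg.n_objects == 0:
        raise ValueError("segmentation contains no objects")
    lo, hi = _parse_window(window)
    span = hi - lo
    nbins = int(round(span / bin_deg))
    if abs(nbins * bin_deg - span) > 1e-9:
        raise ValueError("bin width must divide the window span")
    if radial_band is None:
        a_med = float(np.median([o.minor for o in seg.objects]))
        b_med = float(np.median([o.major for o in seg.objects]))
        a_med = max(a_med, 2 * seg.pixel_size)
        radial_band = (1.0 / (2.0 * b_med), 1.0 / a_med)

    mask = (seg.label_map > 0).astype(float)
    px = seg.pixel_size
    edges = np.linspace(lo, hi, nbins + 1)
    acc = np.zeros(nbins)
    n_sub = 0
    size = min(subimage_px, *mask.shape)
    hann = np.outer(np.hanning(size), np.hanning(size))
    fgrid = np.fft.fftfreq(size, d=px)
    FY, FX = np.meshgrid(fgrid, fgrid, indexing="ij")
    R = np.hypot(FX, FY)
    band_sel = (R >= radial_band[0]) & (R <= radial_band[1])
    # spectral axial angle, rotated 90° into real-space orientation
    spec_angle = axial_deg(np.degrees(np.arctan2(FX, -FY)))
    real_angle = axial_deg(spec_angle + 90.0)
    wangle = _into_window(real_angle, lo, hi)
    usable = band_sel & ~np.isnan(wangle)
    safe_angle = np.nan_to_num(wangle, nan=lo)
    bin_of = np.clip(((safe_angle - lo) / bin_deg).astype(np.int64), 0, nbins - 1)
    # occupancy of the discrete frequency lattice per angular bin: the
    # azimuthal *average* divides by it, else sparse inner radii bias
    occupancy = np.bincount(bin_of[usable].ravel(), minlength=nbins).astype(float)
    occupancy[occupancy == 0] = np.inf

    for sub in _iter_subimages(mask, size):
        if not sub.any():
            continue
        power = np.abs(np.fft.fft2(sub * hann)) ** 2
        hist = np.bincount(bin_of[usable].ravel(), weights=power[usable].ravel(), minlength=nbins)
        hist = hist / occupancy
        total = hist.sum()
        if total <= 0:
            continue
        acc += hist / total if mode == "averaged" else hist
        n_sub += 1
    if n_sub == 0:
        raise ValueError("no subimage contained objects")
    density = acc / acc.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return OrientationDistribution(centers, density, (lo, hi), seg.n_objects, n_sub)


def ellipse_angle_distribution(
    seg: SegmentationResult,
    window="0-90",
    bin_deg: float = 5.0,
) -> OrientationDistribution:
    """Histogram of fitted ellipse angles; oracle for the FFT method."""
    lo, hi = _parse_window(window)
    span = hi - lo
    nbins = int(round(span / bin_deg))
    if abs(nbins * bin_deg - span) > 1e-9:
        raise ValueError("bin width must divide the window span")
    angles = _into_window(np.array([o.angle for o in seg.objects]), lo, hi)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise ValueError("no object angle falls inside the window")
    edges = np.linspace(lo, hi, nbins + 1)
    hist, _ = np.histogram(np.clip(angles, lo, hi - 1e-9), bins=edges)
    density = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return OrientationDistribution(centers, density, (lo, hi), seg.n_objects, 0)


def areal_coverage(
    segs,
    field_area: float,
    cap_corrected: bool = True,
) -> CoverageResult:
    """Percent of the projected field occupied by segmented cells.

    Accepts one segmentation or a list (multiple fields/specimens) and
    reports mean ± sd across them. ``cap_corrected`` uses the
    extrapolated full footprints, which removes the systematic
    undercount caused by thresholding partway up each cell.
    """
    if isinstance(segs, SegmentationResult):
        segs = [segs]
    per_field = []
    for seg in segs:
        total = sum((o.area_full if cap_corrected else o.area) for o in seg.objects)
        per_field.append(100.0 * total / field_area)
    arr = np.asarray(per_field)
    return CoverageResult(
        coverage_pct=float(arr.mean()),
        field_area=field_area,
        n_fields=len(per_field),
        per_field=per_field,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(per_field) > 1 else 0.0,
    )


def profile_morphometrics(
    image: HeightMap,
    center: tuple[float, float],
    angle: float,
    half_length_um: float = 3.0,
    min_prominence: float = 0.05,
    cap_corrected: bool = True,
) -> tuple[float, float]:
    """Cell dimensions from line profiles through its center.

    Extracts height profiles along the cell's major (``angle``) and
    minor (``angle`` + 90°) axes and measures the full width of the
    central peak at half its height above a robust baseline (the 10th
    percentile of the profile — insensitive to surface offset, and
    unlike peak prominence not truncated by adjacent pattern walls when
    the cell sits in a valley). With ``cap_corrected`` the half-height
    width is rescaled by 1/sqrt(3/4) to the full axis length of an
    ellipsoidal cap, whose height falls to half at sqrt(3)/2 of the
    semi-axis. Returns ``(a, b)`` with a ≤ b, in μm.
    """
    px = image.pixel_size
    step = px / 2.0
    t = np.arange(-half_length_um, half_length_um + step / 2, step)

    def width_along(direction_deg: float) -> float:
        dx, dy = direction_vector(direction_deg)
        xs = center[0] + t * dx
        ys = center[1] + t * dy
        coords = np.vstack([ys / px - 0.5, xs / px - 0.5])
        prof = ndimage.map_coordinates(image.values, coords, order=1, mode="nearest")
        peaks, _ = signal.find_peaks(prof, prominence=min_prominence)
        if peaks.size == 0:
            raise ValueError("no peak found on profile: point may not lie on a cell")
        center_idx = t.size // 2
        best = int(peaks[np.argmin(np.abs(peaks - center_idx))])
        base = float(np.percentile(prof, 10.0))
        level = base + 0.5 * (prof[best] - base)

        def crossing(direction: int) -> float:
            i = best
            while 0 < i < prof.size - 1:
                j = i + direction
                if prof[j] < level:
                    # linear interpolation between samples i and j
                    frac = (prof[i] - level) / (prof[i] - prof[j])
                    return abs((i - best) + frac * direction * 1.0)
                i = j
            return abs(i - best)

        return float((crossing(-1) + crossing(+1)) * step)

    scale = 2.0 / math.sqrt(3.0) if cap_corrected else 1.0
    wb = width_along(angle) * scale
    wa = width_along(angle + 90.0) * scale
    return (wa, wb) if wa <= wb else (wb, wa)
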