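"""Synthesis of wrinkled height fields and bilayer wrinkling mechanics.

Implements the classic low-deformation theory for a stiff film bonded to
a compliant substrate: under a compressive strain ε exceeding a critical
value ε_c, the film buckles into sinusoidal wrinkles with

    λ   = 2π h (E̅_f / 3 E̅_s)^(1/3)
    A   = h sqrt(ε/ε_c − 1)
    ε_c = ¼ (3 E̅_s / E̅_f)^(2/3)

where h is the film thickness and E̅ = E/(1 − ν²) are plane-strain
moduli. Four topographies are generated on a regular grid:

* ``F``  — flat reference (optionally dressed with band-limited noise),
* ``1D`` — uniaxial sinusoid,
* ``C``  — checkerboard ("egg-tray"): superposition of two orthogonal
  sinusoids, the second generation attenuated by the amplitude ratio of
  the two wrinkling generations,
* ``H``  — herringbone (chevron): a sinusoid whose wavevector alternates
  by ± half the kink complement across stripes, phase-continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .heightmap import HeightMap

__all__ = [
    "WrinkleMechanics",
    "SurfaceSpec",
    "critical_strain",
    "wrinkle_wavelength",
    "wrinkle_amplitude",
    "film_thickness_for_wavelength",
    "stretched_length",
    "synth_surface",
]

PATTERNS = ("F", "1D", "C", "H")


@dataclass
class WrinkleMechanics:
    """Bilayer parameters of the wrinkling instability.

    Attributes
    ----------
    h : film thickness (μm).
    Ef_bar, Es_bar : plane-strain moduli of film and substrate (MPa).
    nu : Poisson ratio (0.5 is the incompressible-elastomer value).
    epsilon : applied prestrain (dimensionless).
    epsilon_c : critical strain; filled in by :func:`critical_strain`.
    """

    h: float
    Ef_bar: float
    Es_bar: float
    nu: float = 0.5
    epsilon: float = 0.0
    epsilon_c: float | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("film thickness h must be positive")
        if self.Es_bar <= 0 or self.Ef_bar <= 0:
            raise ValueError("moduli must be positive")
        if self.Ef_bar <= self.Es_bar:
            raise ValueError("film must be stiffer than substrate (Ef_bar > Es_bar)")
        if not (0 <= self.nu <= 0.5):
            raise ValueError("Poisson ratio outside [0, 0.5]")


def critical_strain(mech: WrinkleMechanics) -> float:
    """Critical strain ε_c = ¼ (3 E̅_s/E̅_f)^(2/3) for wrinkling onset.

    The result is also stored back into ``mech.epsilon_c``.
    """
    eps_c = 0.25 * (3.0 * mech.Es_bar / mech.Ef_bar) ** (2.0 / 3.0)
    mech.epsilon_c = eps_c
    return eps_c


def wrinkle_wavelength(mech: WrinkleMechanics) -> float:
    """Wrinkle wavelength λ = 2π h (E̅_f / 3 E̅_s)^(1/3) in μm."""
    return 2.0 * math.pi * mech.h * (mech.Ef_bar / (3.0 * mech.Es_bar)) ** (1.0 / 3.0)


def wrinkle_amplitude(mech: WrinkleMechanics) -> float:
    """Wrinkle amplitude A = h sqrt(ε/ε_c − 1) in μm.

    Raises
    ------
    ValueError
        If ε < ε_c (planar regime: no wrinkles below threshold).
    """
    eps_c = mech.epsilon_c if mech.epsilon_c is not None else critical_strain(mech)
    if mech.epsilon < eps_c:
        raise ValueError(
            f"strain {mech.epsilon:g} below critical strain {eps_c:g}: planar regime"
        )
    return mech.h * math.sqrt(mech.epsilon / eps_c - 1.0)


def film_thickness_for_wavelength(wavelength: float, Ef_bar: float, Es_bar: float) -> float:
    """Invert the wavelength relation: h = λ / (2π (E̅_f/3E̅_s)^(1/3))."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength / (2.0 * math.pi * (Ef_bar / (3.0 * Es_bar)) ** (1.0 / 3.0))


def stretched_length(length0: float, strain: float) -> float:
    """Length of a segment of rest length ``length0`` under strain ε.

    ε ≡ (L1 − L0)/L0, so L1 = (1 + ε) L0; the undulated profile produced
    on strain release stores this excess length as wrinkles.
    """
    if length0 <= 0:
        raise ValueError("length must be positive")
    return (1.0 + strain) * length0


@dataclass
class SurfaceSpec:
    """Geometry of one of the four topographies.

    ``orientation`` is the rotation (degrees) of the primary wavevector
    from the N–S frame axis; grooves run perpendicular to the wavevector.
    ``kink_angle`` (H only) is the angle between the two chevron arm
    directions: 180° degenerates to the 1D pattern, the default 90°
    alternates arms at ±45° about the mean groove direction.
    """

    pattern: str
    wavelength_1: float = 2.0
    wavelength_2: float = 2.0
    amplitude_1: float = 0.2
    amplitude_2: float = 0.2
    kink_angle: float = 90.0
    arm_length: float | None = None  # default 4*wavelength_1
    phase_1: float = 0.0
    phase_2: float = 0.0
    orientation: float = 90.0  # wavevector E-W -> grooves along N-S
    c_attenuation: float | None = None  # None -> A2/A1 (second-generation rule)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.wavelength_1 <= 0 or self.wavelength_2 <= 0:
            raise ValueError("wavelengths must be positive")
        if self.amplitude_1 < 0 or self.amplitude_2 < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.pattern == "H" and not (0.0 < self.kink_angle <= 180.0):
            raise ValueError("kink_angle must lie in (0, 180] degrees")
        if self.arm_length is None:
            self.arm_length = 4.0 * self.wavelength_1

    @property
    def groove_angle(self) -> float:
        """Axial angle of the (mean) groove direction from N–S, degrees."""
        from .heightmap import axial_deg

        return axial_deg(self.orientation + 90.0)


def _pattern_field(spec: SurfaceSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Ideal (noise-free) height field at physical coords (μm)."""
    th = math.radians(spec.orientation)
    # coordinate along the primary wavevector and along the mean groove
    P = X * math.sin(th) - Y * math.cos(th)
    Q = X * math.cos(th) + Y * math.sin(th)
    k1 = 2.0 * math.pi / spec.wavelength_1

    if spec.pattern == "F":
        return np.zeros_like(X)
    if spec.pattern == "1D":
        return spec.amplitude_1 * np.sin(k1 * P + spec.phase_1)
    if spec.pattern == "C":
        k2 = 2.0 * math.pi / spec.wavelength_2
        att = (
            spec.c_attenuation
            if spec.c_attenuation is not None
            else (spec.amplitude_2 / spec.amplitude_1 if spec.amplitude_1 > 0 else 1.0)
        )
        a2_eff = att * spec.amplitude_2
        return spec.amplitude_1 * np.sin(k1 * P + spec.phase_1) + a2_eff * np.sin(
            k2 * Q + spec.phase_2
        )
    if spec.pattern == "H":
        # chevron: wavevector alternates by +/- delta about the mean
        # direction in stripes of width arm_length along the groove axis;
        # using a triangle wave T(q) keeps the phase continuous.
        delta = math.radians((180.0 - spec.kink_angle) / 2.0)
        L = float(spec.arm_length)
        m = np.mod(Q, 2.0 * L)
        T = np.where(m < L, m, 2.0 * L - m)
        return spec.amplitude_1 * np.sin(
            k1 * (P * math.cos(delta) + T * math.sin(delta)) + spec.phase_1
        )
    raise ValueError(f"unknown pattern {spec.pattern!r}")


def _calibrated_noise(
    rows: int, cols: int, target_ra: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian height noise rescaled to an exact Ra."""
    white = rng.standard_normal((rows, cols))
    # low-pass at ~4 px (FWHM) emulates finite AFM tip/feedback bandwidth
    smooth = ndimage.gaussian_filter(white, sigma=4.0 / 2.355, mode="reflect")
    smooth -= smooth.mean()
    ra = np.abs(smooth).mean()
    if ra == 0:
        return np.zeros((rows, cols))
    return smooth * (target_ra / ra)


def synth_surface(
    spec: SurfaceSpec,
    rows: int = 512,
    cols: int = 512,
    pixel_size: float = 0.0391,
    noise_Ra: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> HeightMap:
    """Generate a leveled height map for the given topography.

    Parameters
    ----------
    rows, cols, pixel_size
        Grid geometry; for patterned specs the field must span at least
        four wavelengths on each side.
    noise_Ra
        Target arithmetic roughness (μm) of the additive noise
        component; the noise is rescaled so its own Ra matches exactly.
    seed
        Seed (or Generator) controlling the noise; ignored if
        ``noise_Ra`` is 0.

    Returns
    -------
    HeightMap
        Zero-mean height field; ``meta`` records the spec parameters.
    """
    if rows < 4 or cols < 4:
        raise ValueError("grid too small")
    if spec.pattern != "F":
        min_span = 4.0 * max(spec.wavelength_1, spec.wavelength_2 if spec.pattern == "C" else 0.0)
        if rows * pixel_size < min_span or cols * pixel_size < min_span:
            raise ValueError(
                f"field {rows * pixel_size:.3g}×{cols * pixel_size:.3g} μm too small: "
                f"patterned surfaces need ≥ 4 wavelengths ({min_span:.3g} μm) per side"
            )
    x = (np.arange(cols) + 0.5) * pixel_size
    y = (np.arange(rows) + 0.5) * pixel_size
    X, Y = np.meshgrid(x, y)
    z = _pattern_field(spec, X, Y)
    if noise_Ra > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z = z + _calibrated_noise(rows, cols, noise_Ra, rng)
    z = z - z.mean()
    meta = {
        "pattern": spec.pattern,
        "wavelength_1": spec.wavelength_1,
        "amplitude_1": spec.amplitude_1,
        "orientation": spec.orientation,
        "noise_Ra": noise_Ra,
    }
    return HeightMap(z, pixel_size, meta)
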