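"""Shared fixtures: small synthetic surfaces and colonized scans.

Session-scoped where generation is expensive; everything is produced by
the package's own synthesis/simulation modules at fixed seeds.
"""

import numpy as np
import pytest

from wrinklebio.colonization_sim import (
    STRAINS,
    ColonizationModel,
    place_cells,
    render_afm,
)
from wrinklebio.surface_synthesis import SurfaceSpec, synth_surface

FIELD_UM = 20.0
N_PX = 256
PX = FIELD_UM / N_PX


@pytest.fixture(scope="session")
def map_flat():
    return synth_surface(SurfaceSpec("F"), N_PX, N_PX, PX)


@pytest.fixture(scope="session")
def map_flat_noisy():
    return synth_surface(SurfaceSpec("F"), N_PX, N_PX, PX, noise_Ra=0.02, seed=7)


@pytest.fixture(scope="session")
def map_1d():
    """Grooves along N-S (wavevector E-W), λ = 2 μm, A = 0.2 μm."""
    return synth_surface(SurfaceSpec("1D"), N_PX, N_PX, PX)


@pytest.fixture(scope="session")
def map_1d_fine():
    return synth_surface(SurfaceSpec("1D"), 512, 512, FIELD_UM / 512)


@pytest.fixture(scope="session")
def map_c():
    return synth_surface(SurfaceSpec("C", phase_2=0.7), N_PX, N_PX, PX)


@pytest.fixture(scope="session")
def map_h():
    return synth_surface(SurfaceSpec("H"), N_PX, N_PX, PX)


@pytest.fixture(scope="session")
def colonized_1d(map_1d):
    """Rendered scan of rod cells guided along the 1D grooves."""
    rng = np.random.default_rng(2)
    model = ColonizationModel(guidance_strength=8.0)
    placements = place_cells(
        map_1d, STRAINS["E. coli K12"], model, 12.0, rng, valley_width_um=1.0
    )
    image = render_afm(map_1d, placements, noise_rms=0.01, rng=rng)
    return placements, image
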