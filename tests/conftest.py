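import numpy as np
import pytest

from pvctm import virtual_specimen as vs
from pvctm.stack_io import RunConfig

#: scatterer density (particles per voxel) of the standard virtual specimen
SPECKLE_DENSITY = 100_000 / 256 ** 3


def make_speckle(extent, seed, density=SPECKLE_DENSITY, psf_width=2.0):
    n = max(1, int(round(density * np.prod(extent))))
    particles = vs.sample_particles(n, extent, seed)
    return particles, vs.render_stack(particles, extent, psf_width)


@pytest.fixture(scope="session")
def small_cfg():
    """Run configuration matching the confocal defaults but with the axial
    lattice step used by the translation protocols."""
    return RunConfig(step_z=8, smoothing=False)


@pytest.fixture(scope="session")
def speckle_96(request):
    """A 96x96x48 speckle volume at the standard density (session-cached)."""
    particles, stack = make_speckle((96, 96, 48), seed=11)
    return particles, stack


@pytest.fixture(scope="session")
def subpixel_pair(speckle_96):
    """Speckle pair under a known sub-pixel rigid translation."""
    shift = (1.4, -0.6, 2.3)
    particles, before = speckle_96
    field = vs.PrescribedField.translation(shift)
    after = vs.render_stack(vs.deform_particles(particles, field), (96, 96, 48), 2.0)
    return before, after, np.asarray(shift)
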