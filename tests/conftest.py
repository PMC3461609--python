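"""Shared fixtures: the canonical phantom template and PET grid are expensive
enough (seconds) to build once per session."""

import numpy as np
import pytest

from ratpet import QuantConfig, VoxelGrid, run_validation
from ratpet.phantom import PhantomSpec, generate_phantom, generate_template


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def template(spec):
    return generate_template(spec)


@pytest.fixture(scope="session")
def pet_grid(template):
    """Even-extent, origin-centred 1.218 mm grid covering the template."""
    half = np.asarray(template.grid.voxel_size) * np.asarray(template.grid.shape) / 2.0
    shape = []
    for h in half:
        n = int(np.ceil(2.0 * h / 1.218))
        shape.append(n + n % 2)
    return VoxelGrid.centered(tuple(shape), (1.218, 1.218, 1.218))


@pytest.fixture(scope="session")
def identity_phantom(spec, template):
    return generate_phantom(spec, template=template)


@pytest.fixture(scope="session")
def validation_threshold(template, pet_grid):
    return run_validation(template, pet_grid, QuantConfig(inclusion_mode="threshold"))


@pytest.fixture(scope="session")
def validation_fractional(template, pet_grid):
    return run_validation(template, pet_grid, QuantConfig(inclusion_mode="fractional"))
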