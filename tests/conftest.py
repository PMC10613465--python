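"""Shared fixtures: synthetic skull phantoms and their property maps."""

import numpy as np
import pytest

from tfusplan.positioning import TargetSpec
from tfusplan.properties import property_maps
from tfusplan.volumes import PhantomSpec, binarize_skull, generate_phantom


@pytest.fixture(scope="session")
def shell_phantom_spec():
    """Uniform spherical shell emulating a skull: outer radius 26 mm,
    thickness 6 mm, centred target.  The geometry keeps the RP candidate
    shell (ball radius 30 mm minus contact clearance) non-empty and puts
    candidates in the 27-31 mm stimulus-distance band."""
    return PhantomSpec(
        outer_radius=26.0,
        thickness=6.0,
        center=(40.0, 40.0, 40.0),
        target_point=(40.0, 40.0, 40.0),
        shell_hu=700.0,
        background_hu=0.0,
        domain_extent=(80.0, 80.0, 80.0),
        spacing=1.0,
    )


@pytest.fixture(scope="session")
def shell_phantom(shell_phantom_spec):
    return generate_phantom(shell_phantom_spec)


@pytest.fixture(scope="session")
def shell_mask(shell_phantom):
    return binarize_skull(shell_phantom)


@pytest.fixture(scope="session")
def shell_medium(shell_phantom, shell_mask):
    return property_maps(shell_phantom, shell_mask)


@pytest.fixture(scope="session")
def shell_target(shell_phantom_spec):
    return TargetSpec(point=shell_phantom_spec.target_point)


@pytest.fixture(scope="session")
def offset_target_phantom():
    """Shell phantom with the target offset toward the wall, so the RP
    mean-radius rule genuinely excludes part of the search ball."""
    spec = PhantomSpec(
        outer_radius=24.0,
        thickness=5.0,
        center=(32.0, 32.0, 32.0),
        target_point=(32.0, 42.0, 32.0),
        shell_hu=1500.0,
        background_hu=0.0,
        domain_extent=(64.0, 64.0, 64.0),
        spacing=1.0,
    )
    hu = generate_phantom(spec)
    mask = binarize_skull(hu)
    return spec, hu, mask
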