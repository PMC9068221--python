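"""Shared fixtures: phantoms, schemes, and coarse search grids."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nasoplan import (
    LabelScheme,
    LabelVolume,
    SearchGrid,
    generate_channel_phantom,
    generate_skull_phantom,
    standard_phantom_specs,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme() -> LabelScheme:
    return LabelScheme()


@pytest.fixture(scope="session")
def coarse_grid() -> SearchGrid:
    """768-pose grid (45 deg rotations, 90 deg spin, 5 mm travel)."""
    return SearchGrid(rot_step=45, spin_step=90, travel_step=5)


@pytest.fixture(scope="session")
def macaque_vol(scheme) -> LabelVolume:
    """Narrow 2.5 mm channel at 1 mm voxels."""
    return generate_channel_phantom(standard_phantom_specs()["macaque_like"], scheme)


@pytest.fixture(scope="session")
def goat_vol(scheme) -> LabelVolume:
    """Wide 13 mm channel at 0.65 mm voxels."""
    return generate_channel_phantom(standard_phantom_specs()["goat_like"], scheme)


@pytest.fixture(scope="session")
def family_vols(scheme) -> dict[str, LabelVolume]:
    """All five standard phantom families."""
    return {name: generate_skull_phantom(spec, scheme)
            for name, spec in standard_phantom_specs().items()}


@pytest.fixture()
def all_air_vol(scheme) -> LabelVolume:
    """Open 24 mm cube: air everywhere except a small central target blob."""
    labels = np.full((24, 24, 24), scheme.air, dtype=np.int16)
    labels[11:13, 4:6, 11:13] = scheme.target
    return LabelVolume(labels, (1.0, 1.0, 1.0))
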