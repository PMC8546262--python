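"""Shared fixtures: small synthetic heads, layouts and assembled systems.

Unit tests run on deliberately coarse meshes (320 elements per surface);
the acceptance tests build their own meshes at the study densities.
"""

from dataclasses import replace

import numpy as np
import pytest

from lesioncond import (
    EstimationConfig,
    LesionSpec,
    add_spherical_lesion,
    assemble_system,
    make_sphere_head,
    place_electrodes_10_5,
    refine_near_points,
)


@pytest.fixture(scope="session")
def coarse_head():
    """Four-shell sphere head at unit-test resolution (320 faces/surface)."""
    return make_sphere_head(elements_per_surface=320)


@pytest.fixture(scope="session")
def coarse_layout(coarse_head):
    return place_electrodes_10_5(coarse_head.scalp)


@pytest.fixture(scope="session")
def lesioned_head(coarse_head):
    spec = LesionSpec(center=(-49.5, 0.0, 0.0), radius=23.0, conductivity=1.23)
    return add_spherical_lesion(coarse_head, spec, elements=320)


@pytest.fixture(scope="session")
def lesioned_system(lesioned_head):
    return assemble_system(lesioned_head)


@pytest.fixture(scope="session")
def refined_lesioned(lesioned_head, coarse_layout):
    """Lesioned head refined near a fixed temporal pair, with its system."""
    pair = ("T7", "T8")
    pts = np.array([coarse_layout.position_of(p) for p in pair])
    surfs = list(lesioned_head.surfaces)
    for i in (0, 1):
        surfs[i] = refine_near_points(surfs[i], pts, 25.0)
    model = replace(lesioned_head, surfaces=tuple(surfs))
    return model, pair, assemble_system(model)


@pytest.fixture()
def est_config():
    return EstimationConfig(seed=7)
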