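"""Shared fixtures: geometry, meshes and forward bundles are module-scoped
because FEM assembly dominates test runtime."""

from __future__ import annotations

import numpy as np
import pytest

from vagusmap import forward as fw
from vagusmap import phantom as ph
from vagusmap.geometry import NerveGeometry


@pytest.fixture(scope="session")
def geometry() -> NerveGeometry:
    return NerveGeometry()


@pytest.fixture(scope="session")
def small_mesh(geometry) -> fw.Mesh:
    """~1500-element mesh: enough for 1% finite-difference agreement."""
    return fw.build_mesh(geometry, target_elements=1500)


@pytest.fixture(scope="session")
def small_sigma(geometry, small_mesh) -> np.ndarray:
    return small_mesh.base_conductivity(geometry)


@pytest.fixture(scope="session")
def small_jacobian(small_mesh, small_sigma) -> fw.JacobianMatrix:
    return fw.assemble_jacobian(small_mesh, small_sigma)


@pytest.fixture(scope="session")
def voxel_jacobian(small_jacobian, small_mesh) -> fw.JacobianMatrix:
    return fw.voxelize_jacobian(small_jacobian, small_mesh)


@pytest.fixture(scope="session")
def default_phantom(geometry) -> ph.Phantom:
    return ph.make_phantom(geometry, seed=7)
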