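"""Shared fixtures: a coarse fold mesh and its modal basis.

Session-scoped so the FEM assembly and eigen-solve run once; tests must not
mutate these objects.
"""

import numpy as np
import pytest

from vfpinn.geometry import GeometryParams, build_vocal_fold_mesh
from vfpinn.solid import assemble_mass_stiffness, solve_eigenmodes


@pytest.fixture(scope="session")
def coarse_params():
    return GeometryParams(nx=4, ny=3, nz=5)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_params):
    return build_vocal_fold_mesh(coarse_params)


@pytest.fixture(scope="session")
def coarse_system(coarse_mesh):
    return assemble_mass_stiffness(coarse_mesh)


@pytest.fixture(scope="session")
def coarse_basis(coarse_system):
    return solve_eigenmodes(coarse_system, 12)


@pytest.fixture(scope="session")
def default_mesh():
    return build_vocal_fold_mesh(GeometryParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
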