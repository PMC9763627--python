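import numpy as np
import pytest

from rbc_cbmm import (
    AdhesionParams,
    MembraneParams,
    RBCBody,
    TransportParams,
    build_discocyte_mesh,
)
from rbc_cbmm.fixtures import equilateral_patch, flat_patch
from rbc_cbmm.geometry import unit_sphere_mesh


@pytest.fixture(scope="session")
def coarse_discocyte():
    return build_discocyte_mesh(150, 7.8e-6)


@pytest.fixture(scope="session")
def medium_discocyte():
    return build_discocyte_mesh(642, 7.8e-6)


@pytest.fixture()
def perturbed_body(coarse_discocyte):
    rng = np.random.default_rng(7)
    body = RBCBody(coarse_discocyte, MembraneParams())
    scale = 0.03 * coarse_discocyte.rest_edge_lengths.mean()
    body.positions = (coarse_discocyte.vertices
                      + rng.normal(scale=scale, size=body.positions.shape))
    return body


@pytest.fixture(scope="session")
def patch_mesh():
    return flat_patch(21, 21, 100e-9)


@pytest.fixture(scope="session")
def hex_patch():
    return equilateral_patch(10, 100e-9)


@pytest.fixture(scope="session")
def sphere200():
    return unit_sphere_mesh(200)


def make_static_body(mesh, shift=None, density=1.0):
    """Body-like object at rest, optionally translated."""
    body = RBCBody(mesh, MembraneParams())
    if shift is not None:
        body.positions = body.positions + np.asarray(shift)
    body.mfg_density = np.full(mesh.n_vertices, float(density))
    return body


@pytest.fixture()
def table_adhesion():
    """Friction-optimized published adhesion constants (SI)."""
    return AdhesionParams(gamma_ifg=1e-6, gamma_mfg=0.25e-6, beta=0.05e9,
                          r0=20e-9, r_cutoff=100e-9, r_glyco=5e-9,
                          mu_gap=3.6e-3)


@pytest.fixture()
def transport_params():
    return TransportParams(d_mfg=1e-15, delta_fg=45e-9)
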