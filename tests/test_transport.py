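import numpy as np
import pytest

from rbc_cbmm import (
    MembraneParams,
    RBCBody,
    TransportParams,
    adsorption_source,
    average_gap_density,
    contact_query,
    drift_velocity,
    transport_step,
)
from rbc_cbmm.errors import ConfigurationError
from rbc_cbmm.fixtures import flat_patch
from rbc_cbmm.geometry import median_dual_areas, unit_sphere_mesh

from conftest import make_static_body


def _contacted_patch_pair(gap, spacing=100e-9, n=12):
    mesh = flat_patch(n, n, spacing)
    a = make_static_body(mesh)
    b = make_static_body(mesh, shift=[0, 0, gap])
    cm = contact_query(a, b, 200e-9, "vts")
    return a, b, cm


class TestDriftVelocity:
    def test_zero_when_gap_exceeds_mfg_size(self, transport_params):
        # r_sep 56 nm with r_glyco 5 nm -> delta_gap 46 nm > 45 nm
        a, b, cm = _contacted_patch_pair(gap=56e-9)
        b.velocities[:, 0] = 1e-6
        cm = contact_query(a, b, 200e-9, "vts")
        v = drift_velocity(a, cm, transport_params, r_glyco=5e-9)
        assert np.abs(v).max() == 0.0

    def test_zero_gap_gives_half_relative_velocity(self, transport_params):
        # delta_gap = 0 at r_sep = 2*r_glyco -> weight 1 -> drift = w/2
        a, b, cm = _contacted_patch_pair(gap=10e-9)
        w = 2e-6
        b.velocities[:, 0] = w
        cm = contact_query(a, b, 200e-9, "vts")
        v = drift_velocity(a, cm, transport_params, r_glyco=5e-9)
        active = np.abs(v[:, 0]) > 0
        assert active.any()
        assert np.allclose(v[active, 0], 0.5 * w, rtol=1e-9)

    def test_half_gap_gives_quarter_weight(self, transport_params):
        # delta_gap = delta_fg/2 -> drift = 0.25 * relative velocity
        gap = 2 * 5e-9 + 22.5e-9
        a, b, cm = _contacted_patch_pair(gap=gap)
        w = 2e-6
        b.velocities[:, 0] = w
        cm = contact_query(a, b, 200e-9, "vts")
        v = drift_velocity(a, cm, transport_params, r_glyco=5e-9)
        active = np.abs(v[:, 0]) > 0
        assert np.allclose(v[active, 0], 0.25 * w, rtol=1e-6)

    def test_tangential_projection(self, transport_params):
        a, b, cm = _contacted_patch_pair(gap=12e-9)
        b.velocities[:, 0] = 1e-6
        b.velocities[:, 2] = 5e-6     # normal component must be projected out
        cm = contact_query(a, b, 200e-9, "vts")
        v = drift_velocity(a, cm, transport_params, r_glyco=5e-9)
        assert np.abs(v[:, 2]).max() <= 1e-12 * np.abs(v[:, 0]).max()


class TestAdsorptionSource:
    def test_zero_at_equilibrium_density(self, transport_params):
        p = TransportParams(d_mfg=1e-15, adsorption_on=True, phi0=0.01, n0=1.0)
        n = np.full(50, 1.0)
        assert np.abs(adsorption_source(n, None, p)).max() == 0.0

    def test_zero_in_tight_gap(self):
        p = TransportParams(d_mfg=1e-15, adsorption_on=True, phi0=0.01, n0=1.0)
        a, b, cm = _contacted_patch_pair(gap=20e-9)   # < delta_fg = 45nm
        n = np.full(a.mesh.n_vertices, 0.2)
        s = adsorption_source(n, cm, p)
        tight = cm.within_cutoff & (cm.r_vts < p.delta_fg)
        assert tight.any()
        assert np.abs(s[tight]).max() == 0.0
        assert (s[~tight] > 0).all()   # depleted exposed surface replenishes

    def test_replenishment_and_loss_signs(self):
        p = TransportParams(d_mfg=1e-15, adsorption_on=True, phi0=0.05, n0=1.0)
        low = adsorption_source(np.array([0.5]), None, p)
        high = adsorption_source(np.array([1.5]), None, p)
        assert low[0] > 0 and high[0] < 0

    def test_off_flag_returns_zero(self):
        p = TransportParams(adsorption_on=False)
        assert np.abs(adsorption_source(np.array([0.1, 3.0]), None, p)).max() == 0

    def test_phi0_validation(self):
        with pytest.raises(ConfigurationError):
            TransportParams(adsorption_on=True, phi0=-1.0)


class TestTransportStep:
    def test_uniform_field_is_stationary(self, transport_params):
        mesh = unit_sphere_mesh(300)
        body = RBCBody(mesh, MembraneParams())
        transport_step(body, None, None, 10.0, transport_params)
        assert np.abs(body.mfg_density - 1.0).max() == 0.0

    def test_point_release_matches_heat_kernel(self):
        """Variance of a point release grows as 4 D t on a flat sheet."""
        mesh = flat_patch(41, 41, 50e-9)
        body = RBCBody(mesh, MembraneParams())
        areas = median_dual_areas(mesh)
        center = 20 * 41 + 20
        body.mfg_density = np.zeros(mesh.n_vertices)
        body.mfg_density[center] = 1.0 / areas[center]
        p = TransportParams(d_mfg=1e-15)
        t_total, steps = 2.0, 40
        for _ in range(steps):
            transport_step(body, None, None, t_total / steps, p)
        amt = (body.mfg_density * areas).sum()
        xy = body.positions[:, :2] - body.positions[center, :2]
        var = ((xy ** 2).sum(axis=1) * body.mfg_density * areas).sum() / amt
        assert var == pytest.approx(4 * p.d_mfg * t_total, rel=0.05)

    def test_uniform_drift_translates_profile(self):
        """With D = 0 a smooth profile moves at the drift speed."""
        mesh = flat_patch(41, 41, 50e-9)
        body = RBCBody(mesh, MembraneParams())
        areas = median_dual_areas(mesh)
        x = body.positions[:, 0]
        x0 = x.mean()
        body.mfg_density = np.exp(-((x - x0) ** 2) / (2 * (150e-9) ** 2))
        drift = np.zeros_like(body.positions)
        drift[:, 0] = 2e-8
        p = TransportParams(d_mfg=0.0)
        com0 = (x * body.mfg_density * areas).sum() / \
            (body.mfg_density * areas).sum()
        t_total = 10.0
        for _ in range(20):
            transport_step(body, drift, None, t_total / 20, p)
        com1 = (x * body.mfg_density * areas).sum() / \
            (body.mfg_density * areas).sum()
        assert com1 - com0 == pytest.approx(2e-8 * t_total, rel=0.1)

    def test_conservation_with_drift_and_diffusion(self, transport_params):
        mesh = unit_sphere_mesh(400)
        body = RBCBody(mesh, MembraneParams())
        rng = np.random.default_rng(1)
        body.mfg_density = rng.uniform(0.5, 2.0, mesh.n_vertices)
        areas = median_dual_areas(mesh)
        amount0 = (body.mfg_density * areas).sum()
        drift = rng.normal(scale=1e-7, size=body.positions.shape)
        p = TransportParams(d_mfg=1e-13)
        for _ in range(1000):
            transport_step(body, drift, None, 0.01, p)
        amount1 = (body.mfg_density * areas).sum()
        assert abs(amount1 - amount0) <= 1e-8 * amount0
        assert (body.mfg_density >= 0).all()

    def test_diffusion_maximum_principle(self):
        mesh = unit_sphere_mesh(300)
        body = RBCBody(mesh, MembraneParams())
        rng = np.random.default_rng(2)
        body.mfg_density = rng.uniform(0.3, 3.0, mesh.n_vertices)
        lo, hi = body.mfg_density.min(), body.mfg_density.max()
        p = TransportParams(d_mfg=1e-12)
        for _ in range(200):
            transport_step(body, None, None, 0.05, p)
        assert body.mfg_density.min() >= lo - 1e-12
        assert body.mfg_density.max() <= hi + 1e-12


class TestAverageGapDensity:
    def test_baseline_sum_of_two_surfaces(self):
        a, b, cm_ab = _contacted_patch_pair(gap=30e-9)
        cm_ba = contact_query(b, a, 200e-9, "vts")
        nave = average_gap_density([a, b], [cm_ab, cm_ba])
        assert nave == pytest.approx(2.0, rel=1e-9)

    def test_one_surface_zeroed(self):
        a, b, cm_ab = _contacted_patch_pair(gap=30e-9)
        b.mfg_density[:] = 0.0
        cm_ba = contact_query(b, a, 200e-9, "vts")
        nave = average_gap_density([a, b], [cm_ab, cm_ba])
        assert nave == pytest.approx(1.0, rel=1e-9)

    def test_empty_contact_flags_nan(self):
        mesh = flat_patch(6, 6, 100e-9)
        a = make_static_body(mesh)
        b = make_static_body(mesh, shift=[0, 0, 5e-6])
        cm_ab = contact_query(a, b, 100e-9, "vts")
        cm_ba = contact_query(b, a, 100e-9, "vts")
        assert np.isnan(average_gap_density([a, b], [cm_ab, cm_ba]))
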