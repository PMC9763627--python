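import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbc_cbmm import (
    AdhesionParams,
    PathophysParams,
    StateError,
    adhesion_forces,
    contact_query,
    friction_forces,
    morse_energy,
    morse_force_magnitude,
    pathophys_affinity,
    total_affinity,
)
from rbc_cbmm.errors import ConfigurationError
from rbc_cbmm.geometry import median_dual_areas, vertex_normals

from conftest import make_static_body

UJ = 1e-6  # uJ/m^2 in SI


class TestAffinityComposition:
    def test_baseline_composition(self):
        """ΓiFg=1, ΓmFg=0.25 uJ/m^2 with unit densities on both surfaces."""
        p = AdhesionParams(gamma_ifg=1 * UJ, gamma_mfg=0.25 * UJ)
        assert total_affinity(p, 1.0, 1.0) == pytest.approx(1.5 * UJ)

    def test_zero_and_uam_limits(self):
        z = AdhesionParams(beta=0.05e9, r0=20e-9, r_cutoff=100e-9)
        assert total_affinity(z, 5.0, 3.0) == 0.0
        uam = AdhesionParams(gamma_ifgr=0.5 * UJ, gamma_ifg=1 * UJ)
        assert total_affinity(uam, 7.0, 9.0) == pytest.approx(1.5 * UJ)

    def test_negative_density_rejected(self):
        p = AdhesionParams(gamma_mfg=0.25 * UJ)
        with pytest.raises(StateError):
            total_affinity(p, -0.1, 1.0)

    @pytest.mark.parametrize("n_star,g_star,expected_uj,expected_nave", [
        (1.25, 1.0, 1.625, 2.5),   # healthy median
        (1.5, 2.0, 2.5, 3.0),      # SLE median
        (1.0, 1.0, 1.5, 2.0),      # healthy lower = baseline
        (1.5, 1.0, 1.75, 3.0),     # healthy upper
    ])
    def test_pathophysiological_composition(self, n_star, g_star,
                                            expected_uj, expected_nave):
        p = PathophysParams(n_star=n_star, gamma_star=g_star,
                            gamma_mfg_b=0.25 * UJ)
        gamma, nave = pathophys_affinity(p, 1 * UJ)
        assert gamma == pytest.approx(expected_uj * UJ, rel=1e-12)
        assert nave == pytest.approx(expected_nave, rel=1e-12)

    def test_healthy_reference_equals_total_affinity(self):
        p = PathophysParams(n_star=1.0, gamma_star=1.0, gamma_mfg_b=0.25 * UJ)
        gamma, _ = pathophys_affinity(p, 1 * UJ)
        direct = total_affinity(
            AdhesionParams(gamma_ifg=1 * UJ, gamma_mfg=0.25 * UJ), 1.0, 1.0)
        assert gamma == pytest.approx(direct, rel=1e-15)


class TestMorse:
    P = dict(beta=0.05e9, r0=20e-9, rcutoff=100e-9)

    def test_minimum_at_zero_force_separation(self):
        ai = 3e-14
        u0 = morse_energy(20e-9, UJ, area=ai, **self.P)
        assert u0 == pytest.approx(-UJ * ai, rel=1e-12)
        # dense scan: unique minimum at r0, zero force there
        r = np.linspace(0.0, 100e-9, 20001)
        u = morse_energy(r, UJ, area=ai, **self.P)
        assert abs(r[np.argmin(u)] - 20e-9) < 1e-11
        assert morse_force_magnitude(20e-9, UJ, area=ai, **self.P) == 0.0

    def test_zero_beyond_cutoff(self):
        assert morse_energy(101e-9, UJ, area=1e-14, **self.P) == 0.0
        assert morse_force_magnitude(100.001e-9, UJ, area=1e-14, **self.P) == 0.0

    def test_force_is_energy_derivative_along_approach(self):
        # the direction vector points toward the pairing surface (decreasing
        # separation), so the signed force along it is +dU/dr
        r = np.linspace(1e-9, 99e-9, 197)
        h = 1e-13
        ai = 1e-14
        fd = (morse_energy(r + h, UJ, area=ai, **self.P)
              - morse_energy(r - h, UJ, area=ai, **self.P)) / (2 * h)
        f = morse_force_magnitude(r, UJ, area=ai, **self.P)
        # atol covers finite-difference roundoff at the well minimum
        assert np.allclose(f, fd, rtol=1e-6, atol=1e-22)

    def test_sign_convention(self):
        ai = 1e-14
        assert morse_force_magnitude(30e-9, UJ, area=ai, **self.P) > 0  # attract
        assert morse_force_magnitude(10e-9, UJ, area=ai, **self.P) < 0  # repel

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(gamma=st.floats(1e-8, 1e-4), beta=st.floats(1e7, 2e8),
           r0=st.floats(5e-9, 50e-9), rfac=st.floats(0.05, 0.99))
    def test_force_energy_consistency_property(self, gamma, beta, r0, rfac):
        """The force law is the energy derivative along the approach
        direction for arbitrary Morse constants."""
        from hypothesis import assume
        assume(beta * r0 < 6.0)   # keep the exponentials in a well-scaled range
        rcut = 5 * r0
        r = rfac * rcut
        h = 1e-6 * r0
        fd = (morse_energy(r + h, gamma, beta, r0, rcut, 1e-14)
              - morse_energy(r - h, gamma, beta, r0, rcut, 1e-14)) / (2 * h)
        f = morse_force_magnitude(r, gamma, beta, r0, rcut, 1e-14)
        assert f == pytest.approx(fd, rel=1e-4, abs=1e-30)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(g1=st.floats(0, 5e-6), g2=st.floats(0, 5e-6),
           gm=st.floats(0, 5e-6), n1=st.floats(0, 10), n2=st.floats(0, 10))
    def test_affinity_composition_property(self, g1, g2, gm, n1, n2):
        """Composition is additive, symmetric in the two surfaces, and
        reduces to the uniform model when the mobile term vanishes."""
        p = AdhesionParams(gamma_ifgr=g1, gamma_ifg=g2, gamma_mfg=gm)
        tot = total_affinity(p, n1, n2)
        assert tot == pytest.approx(g1 + g2 + (n1 + n2) * gm, rel=1e-12,
                                    abs=1e-30)
        assert tot == pytest.approx(total_affinity(p, n2, n1), rel=1e-12,
                                    abs=1e-30)

    def test_params_validation(self):
        with pytest.raises(ConfigurationError):
            AdhesionParams(r0=200e-9, r_cutoff=100e-9)
        with pytest.raises(ConfigurationError):
            AdhesionParams(gamma_ifg=-1.0)


def _patch_pair(gap, spacing=100e-9, n=15):
    from rbc_cbmm.fixtures import flat_patch
    mesh = flat_patch(n, n, spacing)
    a = make_static_body(mesh)
    b = make_static_body(mesh, shift=[0, 0, gap])
    cm_ab = contact_query(a, b, 100e-9, "vts")
    cm_ba = contact_query(b, a, 100e-9, "vts")
    return a, b, cm_ab, cm_ba


class TestAdhesionForces:
    def test_zero_at_zero_force_separation(self, table_adhesion):
        a, b, cm_ab, cm_ba = _patch_pair(gap=20e-9)
        fa, fb = adhesion_forces(a, b, cm_ab, table_adhesion, cm_ba)
        scale = table_adhesion.gamma_ifg * median_dual_areas(a.mesh).max() \
            * 2 * table_adhesion.beta
        assert np.abs(fa).max() < 1e-9 * scale
        assert np.abs(fb).max() < 1e-9 * scale

    def test_attraction_and_repulsion_sides(self, table_adhesion):
        a, b, cm_ab, cm_ba = _patch_pair(gap=40e-9)
        fa, fb = adhesion_forces(a, b, cm_ab, table_adhesion, cm_ba)
        interior = np.abs(fa[:, 2]) > 0
        assert (fa[interior, 2] > 0).all()   # a pulled up toward b
        assert (fb[np.abs(fb[:, 2]) > 0, 2] < 0).all()
        a, b, cm_ab, cm_ba = _patch_pair(gap=10e-9)
        fa, _ = adhesion_forces(a, b, cm_ab, table_adhesion, cm_ba)
        assert (fa[np.abs(fa[:, 2]) > 0, 2] < 0).all()  # pushed apart

    def test_mobile_term_linear_in_density(self):
        params = AdhesionParams(gamma_mfg=0.25 * UJ)
        a, b, cm_ab, cm_ba = _patch_pair(gap=40e-9)
        f1, _ = adhesion_forces(a, b, cm_ab, params, cm_ba)
        a.mfg_density *= 2
        b.mfg_density *= 2
        f2, _ = adhesion_forces(a, b, cm_ab, params, cm_ba)
        assert np.allclose(f2, 2 * f1, rtol=1e-12)

    def test_momentum_conservation(self, table_adhesion):
        a, b, cm_ab, cm_ba = _patch_pair(gap=35e-9)
        fa, fb = adhesion_forces(a, b, cm_ab, table_adhesion, cm_ba)
        total = fa.sum(axis=0) + fb.sum(axis=0)
        assert np.abs(total).max() <= 1e-12 * np.abs(fa).max()

    def test_uam_equivalence_with_zero_mobile_affinity(self):
        """With Γ_mFg = 0 the pipeline equals the uniform-affinity model
        bit for bit, independent of the density fields."""
        uam = AdhesionParams(gamma_ifg=1.5 * UJ)
        a, b, cm_ab, cm_ba = _patch_pair(gap=40e-9)
        f_ref = adhesion_forces(a, b, cm_ab, uam, cm_ba)
        rng = np.random.default_rng(0)
        a.mfg_density = rng.uniform(0, 5, a.mesh.n_vertices)
        b.mfg_density = rng.uniform(0, 5, b.mesh.n_vertices)
        f_mod = adhesion_forces(a, b, cm_ab, uam, cm_ba)
        assert (f_ref[0] == f_mod[0]).all()
        assert (f_ref[1] == f_mod[1]).all()

    def test_vtv_scheme_on_separated_spheres(self, sphere200):
        # unit-sphere scale: zero-force distance 0.05, cutoff 0.3
        params = AdhesionParams(gamma_ifgr=1 * UJ, r0=0.05, r_cutoff=0.3,
                                beta=60.0)
        a = make_static_body(sphere200)
        b = make_static_body(sphere200, shift=[0, 0, 2.1])
        cm_ab = contact_query(a, b, params.r_cutoff, "vtv")
        cm_ba = contact_query(b, a, params.r_cutoff, "vtv")
        fa, fb = adhesion_forces(a, b, cm_ab, params, cm_ba)
        # net attraction along +z on a, -z on b; momentum conserved
        assert fa[:, 2].sum() > 0
        assert np.abs(fa.sum(axis=0) + fb.sum(axis=0)).max() \
            <= 1e-12 * np.abs(fa).max()

    def test_missing_contact_map_is_state_error(self, table_adhesion):
        a, b, *_ = _patch_pair(gap=40e-9)
        with pytest.raises(StateError):
            adhesion_forces(a, b, None, table_adhesion)


class TestFrictionForces:
    def test_normal_motion_gives_zero(self, table_adhesion):
        a, b, cm_ab, cm_ba = _patch_pair(gap=30e-9)
        a.velocities[:, 2] = 1e-6   # purely normal approach
        cm_ab = contact_query(a, b, 100e-9, "vts")
        cm_ba = contact_query(b, a, 100e-9, "vts")
        fa, fb = friction_forces(a, b, cm_ab, table_adhesion, cm_ba)
        assert np.abs(fa).max() <= 1e-20
        assert np.abs(fb).max() <= 1e-20

    def test_couette_magnitude_and_gap_scaling(self, table_adhesion):
        s = 1e-6
        for gap in (30e-9, 20e-9):
            a, b, cm_ab, cm_ba = _patch_pair(gap=gap)
            a.velocities[:, 0] = s
            cm_ab = contact_query(a, b, 100e-9, "vts")
            cm_ba = contact_query(b, a, 100e-9, "vts")
            fa, _ = friction_forces(a, b, cm_ab, table_adhesion, cm_ba)
            areas = median_dual_areas(a.mesh)
            interior = np.abs(fa[:, 0]) > 0.5 * np.abs(fa[:, 0]).max()
            expect = (table_adhesion.mu_gap * s * areas[interior]
                      / (gap - 2 * table_adhesion.r_glyco))
            assert np.allclose(-fa[interior, 0], expect, rtol=1e-6)

    def test_halved_gap_doubles_force(self, table_adhesion):
        # gaps chosen so the effective Couette gap halves: 30->20 nm
        s = 1e-6
        forces = {}
        for gap in (30e-9, 20e-9):
            a, b, cm_ab, cm_ba = _patch_pair(gap=gap)
            a.velocities[:, 0] = s
            cm_ab = contact_query(a, b, 100e-9, "vts")
            cm_ba = contact_query(b, a, 100e-9, "vts")
            fa, _ = friction_forces(a, b, cm_ab, table_adhesion, cm_ba)
            forces[gap] = np.abs(fa[:, 0]).max()
        assert forces[20e-9] == pytest.approx(2 * forces[30e-9], rel=1e-6)

    def test_friction_power_nonpositive(self, table_adhesion):
        a, b, cm_ab, cm_ba = _patch_pair(gap=30e-9)
        rng = np.random.default_rng(4)
        a.velocities = rng.normal(scale=1e-6, size=a.velocities.shape)
        b.velocities = rng.normal(scale=1e-6, size=b.velocities.shape)
        cm_ab = contact_query(a, b, 100e-9, "vts")
        cm_ba = contact_query(b, a, 100e-9, "vts")
        fa, fb = friction_forces(a, b, cm_ab, table_adhesion, cm_ba)
        power = (np.einsum("ij,ij->", fa, a.velocities)
                 + np.einsum("ij,ij->", fb, b.velocities))
        assert power <= 0.0

    def test_gap_clamp_prevents_singularity(self, table_adhesion):
        a, b, cm_ab, cm_ba = _patch_pair(gap=10.5e-9)  # gap - 2 r_glyco = 0.5nm
        a.velocities[:, 0] = 1e-6
        cm_ab = contact_query(a, b, 100e-9, "vts")
        cm_ba = contact_query(b, a, 100e-9, "vts")
        fa, _ = friction_forces(a, b, cm_ab, table_adhesion, cm_ba)
        areas = median_dual_areas(a.mesh)
        cap = table_adhesion.mu_gap * 1e-6 * areas.max() / table_adhesion.eps_gap
        assert np.isfinite(fa).all()
        assert np.abs(fa).max() <= cap * (1 + 1e-9)
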