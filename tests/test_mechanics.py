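import numpy as np
import pytest

from rbc_cbmm import (
    ConfigurationError,
    MembraneParams,
    RBCBody,
    elastic_forces,
    integrate_step,
    stable_dt,
    strain_energy,
    viscous_forces,
)
from rbc_cbmm.mechanics import internal_forces


class TestMembraneParams:
    def test_k0_consistency_accepted(self):
        p = MembraneParams(k0=0.432)
        assert p.k0_effective == pytest.approx(0.432, rel=1e-3)

    def test_k0_inconsistency_rejected(self):
        with pytest.raises(ConfigurationError, match="K0"):
            MembraneParams(k0=0.5)

    def test_eta_relation(self):
        p = MembraneParams(eta_m=0.7e-6)
        assert p.eta_c == pytest.approx(p.eta_t / 3.0)
        assert p.eta_t == pytest.approx(12 * 0.7e-6 / (13 * np.sqrt(3)))


class TestElasticForces:
    def test_rest_state_is_equilibrium(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams())
        f = elastic_forces(body)
        # typical force scale for a small perturbation of the same body
        probe = body.positions.copy()
        probe[0] += 1e-9
        scale = np.abs(elastic_forces(body, probe)).max()
        assert np.abs(f).max() <= 1e-9 * max(scale, 1e-30) + 1e-25

    def test_translation_invariance(self, perturbed_body):
        f0 = elastic_forces(perturbed_body)
        shifted = perturbed_body.positions + np.array([1e-6, -2e-6, 3e-6])
        f1 = elastic_forces(perturbed_body, shifted)
        assert np.allclose(f0, f1, rtol=0, atol=1e-9 * np.abs(f0).max())
        # net force vanishes (translation invariance of the energy)
        assert np.abs(f0.sum(axis=0)).max() <= 1e-12 * np.abs(f0).max()

    def test_matches_finite_difference_gradient(self, perturbed_body):
        body = perturbed_body
        f = elastic_forces(body)
        rng = np.random.default_rng(11)
        h = 1e-12
        scale = np.abs(f).max()
        for vi in rng.choice(body.mesh.n_vertices, 8, replace=False):
            for c in range(3):
                xp = body.positions.copy()
                xm = body.positions.copy()
                xp[vi, c] += h
                xm[vi, c] -= h
                fd = -(strain_energy(body, xp)["total"]
                       - strain_energy(body, xm)["total"]) / (2 * h)
                assert abs(fd - f[vi, c]) <= 1e-5 * scale

    def test_each_energy_term_consistent(self, perturbed_body):
        """Per-term gradient check: zeroing the other moduli isolates each
        energy contribution against finite differences."""
        mesh = perturbed_body.mesh
        x = perturbed_body.positions
        cases = {
            "shear": MembraneParams(eb=0, ka=0, kd=0, k_omega=0),
            "bend": MembraneParams(es0=0, ka=0, kd=0, k_omega=0),
            "area": MembraneParams(es0=0, eb=0, k_omega=0),
            "volume": MembraneParams(es0=0, eb=0, ka=0, kd=0),
        }
        rng = np.random.default_rng(5)
        h = 1e-12
        for name, params in cases.items():
            body = RBCBody(mesh, params, positions=x.copy())
            f = elastic_forces(body)
            scale = max(np.abs(f).max(), 1e-30)
            for vi in rng.choice(mesh.n_vertices, 4, replace=False):
                for c in range(3):
                    xp = x.copy()
                    xm = x.copy()
                    xp[vi, c] += h
                    xm[vi, c] -= h
                    fd = -(strain_energy(body, xp)["total"]
                           - strain_energy(body, xm)["total"]) / (2 * h)
                    assert abs(fd - f[vi, c]) <= 1e-5 * scale, name

    def test_kernel_equals_reference_path(self, perturbed_body):
        body = perturbed_body
        rng = np.random.default_rng(2)
        body.velocities = rng.normal(scale=1e-6, size=body.velocities.shape)
        fused = internal_forces(body)
        ref = elastic_forces(body) + viscous_forces(body)
        assert np.allclose(fused, ref, rtol=1e-12,
                           atol=1e-14 * np.abs(ref).max())


class TestViscousForces:
    def test_rigid_translation_gives_zero(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams())
        body.velocities = np.tile([1e-6, -2e-6, 0.5e-6],
                                  (coarse_discocyte.n_vertices, 1))
        assert np.abs(viscous_forces(body)).max() == 0.0

    def test_pair_closing_speed_force(self):
        """Two vertices approaching along their edge: |F| = (eta_T+eta_C)s."""
        import rbc_cbmm.fixtures as fx
        mesh = fx.flat_patch(2, 2, 1e-6)
        p = MembraneParams()
        body = RBCBody(mesh, p)
        # move vertex 0 toward vertex 2 (same x row) along the connecting edge
        e = body.positions[2] - body.positions[0]
        ehat = e / np.linalg.norm(e)
        s = 1e-6
        body.velocities[0] = s * ehat
        f = viscous_forces(body)
        expected = (p.eta_t + p.eta_c) * s
        assert np.dot(f[0], -ehat) == pytest.approx(expected, rel=1e-12)

    def test_momentum_and_dissipation(self, perturbed_body):
        rng = np.random.default_rng(3)
        perturbed_body.velocities = rng.normal(
            scale=1e-6, size=perturbed_body.velocities.shape)
        f = viscous_forces(perturbed_body)
        assert np.abs(f.sum(axis=0)).max() <= 1e-12 * np.abs(f).max()
        power = np.einsum("ij,ij->", f, perturbed_body.velocities)
        assert power <= 0.0


class TestIntegration:
    def test_free_drift_exact(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams(
            es0=0, eb=0, ka=0, kd=0, k_omega=0, eta_m=0))
        v = np.array([1e-6, 2e-6, -1e-6])
        body.velocities = np.tile(v, (coarse_discocyte.n_vertices, 1))
        x0 = body.positions.copy()
        dt = 1e-3
        for _ in range(10):
            integrate_step([body], None, dt)
        assert np.allclose(body.positions, x0 + 10 * dt * v, rtol=1e-12)

    def test_constant_force_velocity_closed_form(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams(
            es0=0, eb=0, ka=0, kd=0, k_omega=0, eta_m=0))
        fext = np.zeros_like(body.positions)
        fext[:, 0] = 1e-12
        dt, n = 1e-3, 25
        for _ in range(n):
            integrate_step([body], [fext], dt)
        expected = 1e-12 * n * dt / body.vertex_mass
        assert np.allclose(body.velocities[:, 0], expected, rtol=1e-12)

    def test_dt_above_bound_rejected(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams())
        bad_dt = 10 * stable_dt([body], safety=1.0)
        with pytest.raises(ConfigurationError, match="stability"):
            integrate_step([body], None, bad_dt, dt_check=True)

    def test_self_convergence_under_dt_refinement(self, coarse_discocyte):
        """First-order self convergence of the damped relaxation dynamics."""
        def run(dt, n):
            body = RBCBody(coarse_discocyte, MembraneParams())
            body.positions = coarse_discocyte.vertices * 1.002
            for _ in range(n):
                integrate_step([body], None, dt)
            return body.positions

        dt0 = stable_dt([RBCBody(coarse_discocyte, MembraneParams())]) / 4
        x1 = run(dt0, 128)
        x2 = run(dt0 / 2, 256)
        x4 = run(dt0 / 4, 512)
        e12 = np.abs(x1 - x2).max()
        e24 = np.abs(x2 - x4).max()
        assert e24 < 0.75 * e12  # error shrinks with dt

    def test_relaxation_dissipates_energy(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams())
        body.positions = coarse_discocyte.vertices * 1.003
        dt = stable_dt([body])
        energies = []
        for k in range(2500):
            integrate_step([body], None, dt)
            if k % 250 == 0:
                ke = 0.5 * body.vertex_mass * np.einsum(
                    "ij,ij->", body.velocities, body.velocities)
                energies.append(strain_energy(body)["total"] + ke)
        diffs = np.diff(energies)
        assert (diffs <= 1e-12 * energies[0]).all()
        assert energies[-1] < 0.9 * energies[0]


class TestStableDt:
    def test_scaling_with_stiffness_and_mass(self, coarse_discocyte):
        # isolate the edge-spring term so the scaling is clean
        base = RBCBody(coarse_discocyte, MembraneParams(ka=0, kd=0, eta_m=0))
        stiff = RBCBody(coarse_discocyte,
                        MembraneParams(es0=4 * 6.54e-6, ka=0, kd=0, eta_m=0))
        heavy = RBCBody(coarse_discocyte,
                        MembraneParams(ka=0, kd=0, eta_m=0,
                                       mass_total=4 * 2.4e-6))
        dt0 = stable_dt([base])
        assert stable_dt([stiff]) == pytest.approx(dt0 / 2, rel=1e-6)
        assert stable_dt([heavy]) == pytest.approx(2 * dt0, rel=1e-6)

    def test_rest_mesh_stays_put(self, coarse_discocyte):
        body = RBCBody(coarse_discocyte, MembraneParams())
        dt = stable_dt([body])
        x0 = body.positions.copy()
        for _ in range(10000):
            integrate_step([body], None, dt)
        assert np.abs(body.positions - x0).max() < 1e-9
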