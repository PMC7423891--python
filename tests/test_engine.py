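"""Engine-level checks: pair potentials, force consistency, minimization,
integrator contracts, and the stiff-spring compatibility mode."""

import math

import numpy as np
import pytest

from mtwedge import engine, flexible
from mtwedge.engine import (
    EngineInstability, build_protofilament_chain, compute_forces, minimize,
    pair_energy_wca, site_energy, step_langevin)
from mtwedge.params import ModelParameters


class TestPotentials:
    def test_wca_values(self, params):
        cut = 2 ** (1 / 6)
        assert pair_energy_wca(cut, params) == pytest.approx(0.0, abs=1e-12)
        assert pair_energy_wca(1.0, params) == pytest.approx(1.0)
        assert pair_energy_wca(3.0, params) == 0.0
        with pytest.raises(ValueError):
            pair_energy_wca(0.0, params)

    def test_site_energy_values(self, params):
        assert site_energy(0.0, 4.8, params) == pytest.approx(-9.6)
        assert site_energy(params.site_cutoff, 4.8, params) == 0.0
        assert site_energy(0.3, 0.0, params) == 0.0
        # continuity at the cutoff
        rc = params.site_cutoff
        assert site_energy(rc - 1e-9, 4.8, params) == pytest.approx(0.0, abs=1e-6)


class TestForces:
    def test_distant_subunits_no_force(self, params, templates):
        n = 2
        st = engine.SimulationState(
            params=params, templates=templates,
            body_type=np.zeros(n, np.int8),
            pos=np.array([[0.0, 0, 0], [30.0, 0, 0]]),
            quat=np.tile([1.0, 0, 0, 0], (n, 1)),
            vel=np.zeros((n, 3)), angmom=np.zeros((n, 3)),
            immobile=np.zeros(n, bool), culled=np.zeros(n, bool))
        f, t, e = compute_forces(st)
        assert e == 0.0
        assert np.abs(f).max() == 0.0 and np.abs(t).max() == 0.0

    def test_finite_difference_consistency(self, params):
        """Forces and torques match central differences of the energy."""
        st = build_protofilament_chain(1, params, compressed=True)
        rng = np.random.default_rng(7)
        st.pos += 0.05 * rng.standard_normal(st.pos.shape)
        st.quat = engine._normalize(st.quat + 0.02 * rng.standard_normal(st.quat.shape))
        f, t, e = compute_forces(st)
        eps = 1e-6
        for i in range(2):
            for k in range(3):
                s1 = st.copy()
                s1.pos[i, k] += eps
                s2 = st.copy()
                s2.pos[i, k] -= eps
                fd = -(compute_forces(s1)[2] - compute_forces(s2)[2]) / (2 * eps)
                assert abs(fd - f[i, k]) < 1e-4
                s1 = st.copy()
                s2 = st.copy()
                dphi = np.zeros((1, 3))
                dphi[0, k] = eps
                s1.quat[i] = engine._normalize(engine.quat_mul(
                    engine.quat_from_rotvec(dphi), s1.quat[i:i + 1]))[0]
                dphi[0, k] = -eps
                s2.quat[i] = engine._normalize(engine.quat_mul(
                    engine.quat_from_rotvec(dphi), s2.quat[i:i + 1]))[0]
                fd = -(compute_forces(s1)[2] - compute_forces(s2)[2]) / (2 * eps)
                assert abs(fd - t[i, k]) < 1e-4

    def test_interior_subunits_force_free_in_register(self, params):
        from mtwedge.lattice import LatticeConfiguration, build_microtubule
        cfg = LatticeConfiguration.uniform(6, 1.0)
        state = build_microtubule(cfg, params)
        f, t, _ = compute_forces(state)
        assert np.abs(f).max() < 1e-3


class TestMinimize:
    def test_already_minimized_unchanged(self, params):
        st = build_protofilament_chain(3, params, compressed=False)
        pos0 = st.pos.copy()
        out, info = minimize(st, force_tol=1e-5)
        assert info.converged
        assert np.abs(out.pos - pos0).max() < 1e-8

    def test_perturbed_chain_returns_to_minimum(self, params):
        st = build_protofilament_chain(3, params, compressed=False)
        ref = st.pos.copy()
        rng = np.random.default_rng(1)
        st.pos += 0.05 * rng.standard_normal(st.pos.shape)
        out, info = minimize(st, force_tol=1e-6, max_iter=10000)
        assert info.converged
        # same basin: positions recover up to a global rigid transform
        a = out.pos - out.pos.mean(axis=0)
        b = ref - ref.mean(axis=0)
        u, _, vt = np.linalg.svd(a.T @ b)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        assert np.abs(a @ rot - b).max() < 1e-2

    def test_energy_descent(self, params):
        st = build_protofilament_chain(4, params, compressed=True)
        energies = []
        state = st.copy()
        for _ in range(6):
            state, info = minimize(state, force_tol=1e-12, max_iter=150,
                                   copy=False)
            energies.append(info.energy)
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


class TestIntegrator:
    def test_nve_energy_drift(self):
        p = ModelParameters(temperature=0.0, damping=0.0)
        st = build_protofilament_chain(3, p, compressed=True)
        rng = np.random.default_rng(5)
        st.vel += 0.1 * rng.standard_normal(st.vel.shape)
        st.angmom += 0.3 * rng.standard_normal(st.angmom.shape)
        e0 = engine.total_energy(st)
        step_langevin(st, 10000, rng_seed=1)
        e1 = engine.total_energy(st)
        assert abs(e1 - e0) / 10000 < 1e-5

    def test_determinism_under_fixed_seed(self, params):
        a = build_protofilament_chain(2, params, compressed=True)
        b = a.copy()
        step_langevin(a, 500, rng_seed=42)
        step_langevin(b, 500, rng_seed=42)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.quat, b.quat)
        assert np.array_equal(a.vel, b.vel)

    def test_zero_temperature_lattice_is_static(self, params):
        from mtwedge.lattice import LatticeConfiguration, build_microtubule
        p = params.replace(temperature=0.0)
        cfg = LatticeConfiguration.uniform(5, 1.0)
        st = build_microtubule(cfg, p)
        ref = st.pos.copy()
        step_langevin(st, 10000, rng_seed=2)
        assert np.abs(st.pos - ref).max() < 1e-3

    def test_instability_aborts_with_diagnostics(self, params):
        st = build_protofilament_chain(2, params, compressed=False)
        st.vel[:] = 1000.0
        with pytest.raises(EngineInstability) as exc:
            step_langevin(st, 10, rng_seed=0)
        assert "vmax" in exc.value.diagnostics

    def test_immobile_subunits_do_not_move(self, params):
        st = build_protofilament_chain(3, params, compressed=True)
        st.immobile[:2] = True
        ref = st.pos[:2].copy()
        step_langevin(st, 1000, rng_seed=9)
        assert np.array_equal(st.pos[:2], ref)


class TestFlexibleMode:
    def test_shape_retained_by_stiff_springs(self, params):
        """Time-averaged intra-subunit distances stay within 1% of template."""
        st = build_protofilament_chain(1, params, compressed=True)
        fs = flexible.from_rigid_state(st)
        rng = np.random.default_rng(3)
        flexible.step_langevin_flexible(fs, 1000, rng=rng)
        acc = np.zeros_like(fs.spring_r0)
        n = 40
        for _ in range(n):
            flexible.step_langevin_flexible(fs, 100, rng=rng)
            acc += np.linalg.norm(fs.pos[fs.spring_i] - fs.pos[fs.spring_j],
                                  axis=1)
        dbar = acc / n
        sel = fs.spring_r0 > 0.5  # relative deviation meaningful
        rel = np.abs(dbar[sel] / fs.spring_r0[sel] - 1.0)
        assert rel.mean() < 0.01
        assert rel.max() < 0.03
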