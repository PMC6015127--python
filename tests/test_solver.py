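"""Step-loop semantics: prediction, projection, velocity update, damping,
conservation and determinism."""

import numpy as np
import pytest

from threadsim import quaternion as quat
from threadsim.solver import (
    World,
    apply_damping,
    compute_residuals,
    predict_state,
    project_constraints,
    step,
    update_velocities,
)
from threadsim.state import SimConfig, build_rod, make_spiral_centerline

from conftest import random_unit_quaternion


def straight_rod(n_particles=6, d=0.01, **kw):
    pts = np.zeros((n_particles, 3))
    pts[:, 2] = np.arange(n_particles) * d
    return build_rod(pts, radius=d / 2, **kw)


def make_world(rod_states, **cfg_kw):
    cfg_kw.setdefault("collision_enabled", False)
    return World.from_rods(rod_states, SimConfig(**cfg_kw))


class TestPredict:
    def test_zero_velocity_zero_force_is_identity(self):
        world = make_world([straight_rod()], gravity=(0, 0, 0))
        x0 = world.x.copy()
        predict_state(world)
        assert np.abs(world.x - x0).max() == 0.0

    def test_gravity_only_analytic(self):
        world = make_world([straight_rod()], dt=0.01)
        predict_state(world)
        assert np.allclose(world.v[:, 1], -0.0981, atol=1e-12)
        assert np.allclose(world.x[:, 1], -9.81e-4, atol=1e-12)

    def test_spin_integrates_to_half_turn(self):
        # ω = (0,0,π) for 1 s in fine substeps ≈ 180° rotation about e3
        rod, ps, os_ = straight_rod(3)
        world = make_world([(rod, ps, os_)], gravity=(0, 0, 0), dt=1e-4)
        world.omega[:] = [0.0, 0.0, np.pi]
        for _ in range(10000):
            predict_state(world)
        expected = quat.from_axis_angle([0, 0, 1.0], np.pi)
        for q in world.q:
            assert min(np.abs(q - expected).max(), np.abs(q + expected).max()) < 1e-3

    def test_fixed_variables_do_not_move(self):
        rod, ps, os_ = straight_rod()
        ps.inverse_masses[0] = 0.0
        os_.inverse_inertias[0] = 0.0
        world = make_world([(rod, ps, os_)])
        world.omega[:] = 1.0
        x0, q0 = world.x[0].copy(), world.q[0].copy()
        predict_state(world)
        assert np.abs(world.x[0] - x0).max() == 0.0
        assert np.abs(world.q[0] - q0).max() == 0.0


class TestVelocityUpdate:
    def test_no_motion_gives_zero(self):
        world = make_world([straight_rod()])
        xb, qb = world.x.copy(), world.q.copy()
        update_velocities(world, xb, qb, 0.01)
        assert np.abs(world.v).max() == 0.0
        assert np.abs(world.omega).max() == 0.0

    def test_pure_translation(self):
        world = make_world([straight_rod()])
        xb = world.x.copy()
        qb = world.q.copy()
        world.x[:] += [1e-3, 0, 0]
        update_velocities(world, xb, qb, 0.01)
        assert np.allclose(world.v, [0.1, 0, 0], atol=1e-12)

    def test_small_rotation_angular_velocity(self):
        world = make_world([straight_rod()])
        xb, qb = world.x.copy(), world.q.copy()
        world.q[:] = quat.multiply(quat.from_axis_angle([0, 1.0, 0], 0.01), world.q)
        update_velocities(world, xb, qb, 0.01)
        assert np.abs(world.omega - [0.0, 1.0, 0.0]).max() < 1e-4

    def test_predict_update_roundtrip(self):
        # update_velocities recovers exactly the ω that predict applied
        rod, ps, os_ = straight_rod(3)
        world = make_world([(rod, ps, os_)], gravity=(0, 0, 0), dt=0.005)
        world.omega[:] = [0.3, -1.2, 0.7]
        om = world.omega.copy()
        xb, qb = world.x.copy(), world.q.copy()
        predict_state(world)
        update_velocities(world, xb, qb, 0.005)
        assert np.abs(world.omega - om).max() < 1e-3


class TestDamping:
    def test_zero_damping_identity(self, rng):
        v = rng.standard_normal((4, 3))
        om = rng.standard_normal((3, 3))
        v2, om2 = apply_damping(v, om, 0.0, 0.0, 1 / 60)
        assert np.abs(v2 - v).max() == 0.0
        assert np.abs(om2 - om).max() == 0.0

    def test_half_damping_over_one_second(self):
        v = np.ones((1, 3))
        v2, _ = apply_damping(v, np.zeros((1, 3)), 0.5, 0.0, 1.0)
        assert np.allclose(v2, 0.5, atol=1e-15)

    def test_power_law_time_step_independence(self):
        om = np.ones((1, 3))
        _, om2 = apply_damping(np.zeros((1, 3)), om, 0.0, 0.75, 0.5)
        assert np.allclose(om2, 0.25**0.5, atol=1e-15)

    def test_full_damping_zeroes_velocities(self, rng):
        v = rng.standard_normal((5, 3))
        om = rng.standard_normal((4, 3))
        v2, om2 = apply_damping(v, om, 1.0, 1.0, 1.0)
        assert np.abs(v2).max() == 0.0
        assert np.abs(om2).max() == 0.0


class TestStep:
    def test_free_fall_matches_closed_form(self):
        # unconstrained single-element rod: symplectic Euler has the exact
        # discrete solution x_n = x0 - g dt² n(n+1)/2
        rod, ps, os_ = straight_rod(2, damping_linear=0.0, damping_angular=0.0)
        world = make_world([(rod, ps, os_)], dt=1 / 120, use_ddc=False)
        y0 = world.x[:, 1].copy()
        n = 120
        for _ in range(n):
            step(world, compute_report=False)
        dt = 1 / 120
        discrete = y0 - 9.81 * dt**2 * n * (n + 1) / 2
        assert np.abs(world.x[:, 1] - discrete).max() < 1e-9
        continuous = y0 - 0.5 * 9.81 * (n * dt) ** 2
        assert np.abs(world.x[:, 1] - continuous).max() < 9.81 * (n * dt) * dt

    def test_pinned_rod_settles_vertical(self):
        rod, ps, os_ = straight_rod(2, d=0.02, damping_linear=0.8)
        ps.inverse_masses[0] = 0.0
        world = make_world([(rod, ps, os_)])
        for _ in range(3000):
            step(world, compute_report=False)
        direction = world.x[1] - world.x[0]
        direction /= np.linalg.norm(direction)
        assert direction @ np.array([0.0, -1.0, 0.0]) > 0.995

    def test_deterministic_across_runs(self):
        def run():
            pts = make_spiral_centerline(0.05, 20, 0.003, 0.004, axis=(0, -1, 0))
            rod, ps, os_ = build_rod(pts, radius=0.05 / 40)
            ps.inverse_masses[0] = 0.0
            world = make_world([(rod, ps, os_)], dt=1 / 240)
            for _ in range(100):
                step(world, compute_report=False)
            return world.x.copy(), world.v.copy(), world.q.copy()

        x1, v1, q1 = run()
        x2, v2, q2 = run()
        assert np.array_equal(x1, x2) and np.array_equal(v1, v2) and np.array_equal(q1, q2)

    def test_held_particles_never_move(self):
        rod, ps, os_ = straight_rod(8)
        ps.inverse_masses[0] = 0.0
        ps.inverse_masses[4] = 0.0
        world = make_world([(rod, ps, os_)])
        held0 = world.x[[0, 4]].copy()
        for _ in range(200):
            step(world, compute_report=False)
        assert np.array_equal(world.x[[0, 4]], held0)

    def test_quaternion_norms_preserved(self):
        pts = make_spiral_centerline(0.05, 20, 0.003, 0.004, axis=(0, -1, 0))
        rod, ps, os_ = build_rod(pts, radius=0.05 / 40)
        ps.inverse_masses[0] = 0.0
        world = make_world([(rod, ps, os_)], dt=1 / 240)
        for _ in range(200):
            step(world, compute_report=False)
            norms = np.linalg.norm(world.q, axis=1)
            assert np.abs(norms - 1.0).max() < 1e-9


class TestProjection:
    def test_internal_constraints_conserve_linear_momentum(self, rng):
        # free rod (no pins, no gravity): Σ mᵢ Δpᵢ = 0 over the projection
        pts = make_spiral_centerline(0.05, 20, 0.003, 0.004)
        rod, ps, os_ = build_rod(pts, radius=0.05 / 40)
        ps.positions += rng.standard_normal(ps.positions.shape) * 2e-4
        world = make_world([(rod, ps, os_)], iterations=10)
        com0 = world.x.sum(axis=0)  # unit masses
        project_constraints(world, None)
        assert np.abs(world.x.sum(axis=0) - com0).max() < 1e-10

    def test_residual_non_increasing_on_static_rod(self, rng):
        rod, ps, os_ = straight_rod(12)
        ps.positions += rng.standard_normal(ps.positions.shape) * 5e-5
        world = make_world([(rod, ps, os_)], iterations=1)

        def stacked_residual():
            r = compute_residuals(world)
            return np.sqrt(
                r["shear_stretch"] ** 2 + r["bend_twist"] ** 2 + r["distance"] ** 2
            )

        prev = stacked_residual()
        for _ in range(25):
            project_constraints(world, None)
            cur = stacked_residual()
            assert cur <= prev + 1e-12
            prev = cur

    def test_distance_projection_symmetric_split(self):
        # classic closed form: equal masses stretched by 2ε → each endpoint
        # moves ε toward the other along the segment direction
        d = 0.01
        eps = 1e-3
        pts = np.zeros((2, 3))
        pts[1, 2] = d
        rod, ps, os_ = build_rod(pts, radius=d / 2, stiffness_bend=1.0)
        ps.positions[1, 2] = d + 2 * eps
        world = make_world([(rod, ps, os_)], iterations=1, use_ddc=True)
        project_constraints(world, None)
        assert world.x[0, 2] == pytest.approx(eps, abs=1e-9)
        assert world.x[1, 2] == pytest.approx(d + eps, abs=1e-9)

    def test_one_endpoint_fixed_absorbs_whole_correction(self):
        d = 0.01
        pts = np.zeros((2, 3))
        pts[1, 2] = d
        rod, ps, os_ = build_rod(pts, radius=d / 2)
        ps.positions[1, 2] = d * 1.2
        ps.inverse_masses[0] = 0.0
        world = make_world([(rod, ps, os_)], iterations=1)
        project_constraints(world, None)
        assert np.abs(world.x[0]).max() == 0.0
        assert world.x[1, 2] == pytest.approx(d, abs=1e-9)

    def test_one_pass_matches_independent_gauss_seidel_oracle(self, rng):
        """One Gauss–Seidel sweep equals a straight-line reimplementation of
        the mass-weighted projection (λ = −(JWJᵀ)⁻¹C, Δp = WJᵀλ) applied
        constraint by constraint with dense linear algebra."""
        d = 0.01
        pts = np.zeros((5, 3))
        pts[:, 2] = np.arange(5) * d
        rod, ps, os_ = build_rod(pts, radius=d / 2)
        ps.positions += rng.standard_normal((5, 3)) * 1e-3
        os_.quaternions[:] = quat.normalize(
            os_.quaternions + 0.05 * rng.standard_normal((4, 4))
        )
        x_oracle = ps.positions.copy()
        q_oracle = os_.quaternions.copy()
        winv = ps.inverse_masses.copy()
        winvq = os_.inverse_inertias.copy()
        e3 = np.array([0.0, 0.0, 1.0])

        def d3_jac(q):
            w, x, y, z = q
            return 2.0 * np.array(
                [[y, z, w, x], [-x, -w, z, y], [w, -x, -y, z]]
            )

        # shear–stretch sweep
        for i in range(rod.element_count):
            q_oracle[i] /= np.linalg.norm(q_oracle[i])
            q = q_oracle[i]
            C = (x_oracle[i + 1] - x_oracle[i]) / d - quat.to_matrix(q) @ e3
            Jp1 = -np.eye(3) / d
            Jp2 = np.eye(3) / d
            Jq = -d3_jac(q)
            A = (
                winv[i] * Jp1 @ Jp1.T
                + winv[i + 1] * Jp2 @ Jp2.T
                + winvq[i] * Jq @ Jq.T
            )
            lam = np.linalg.solve(A, -C) * rod.stiffness_stretch
            x_oracle[i] += winv[i] * Jp1.T @ lam
            x_oracle[i + 1] += winv[i + 1] * Jp2.T @ lam
            q_oracle[i] += winvq[i] * Jq.T @ lam
            q_oracle[i] /= np.linalg.norm(q_oracle[i])
        # bend–twist sweep
        for i in range(rod.element_count - 1):
            q = q_oracle[i] / np.linalg.norm(q_oracle[i])
            u = q_oracle[i + 1] / np.linalg.norm(q_oracle[i + 1])
            rel = quat.multiply(quat.conjugate(q), u)
            if rel @ rod.rest_relative[i] < 0:
                u = -u
                q_oracle[i + 1] = u
                rel = quat.multiply(quat.conjugate(q), u)
            C = quat.imaginary(rel - rod.rest_relative[i])
            qw, qv = q[0], q[1:]
            uw, uv = u[0], u[1:]

            def skew(v):
                return np.array(
                    [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
                )

            Jq = np.column_stack([uv, -uw * np.eye(3) + skew(uv)])
            Ju = np.column_stack([-qv, qw * np.eye(3) - skew(qv)])
            A = winvq[i] * Jq @ Jq.T + winvq[i + 1] * Ju @ Ju.T
            scale = np.array(
                [rod.stiffness_bend, rod.stiffness_bend, rod.stiffness_twist]
            )
            lam = np.linalg.solve(A, -C) * scale
            q_oracle[i] = q + winvq[i] * Jq.T @ lam
            q_oracle[i + 1] = u + winvq[i + 1] * Ju.T @ lam
            q_oracle[i] /= np.linalg.norm(q_oracle[i])
            q_oracle[i + 1] /= np.linalg.norm(q_oracle[i + 1])

        world = make_world([(rod, ps, os_)], iterations=1, use_ddc=False)
        project_constraints(world, None)
        assert np.abs(world.x - x_oracle).max() < 1e-10
        assert np.abs(world.q - q_oracle).max() < 1e-10
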