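"""Clot force model, wall handling, and trajectory outcomes."""

import numpy as np
import pytest

from emboflow.clot_transport import (
    Clot,
    ForceModel,
    advance_clot,
    classify_outcome,
    drag_coefficient,
    simulate_clots,
    wall_interact,
    _Batch,
)
from emboflow.geometry import build_arch
from emboflow.hemodynamics import BloodProperties, ejection_times

BLOOD = BloodProperties()


class TestDragCoefficient:
    def test_stokes_limit(self):
        """C_d Re / 24 -> 1 as Re -> 0."""
        re = 1e-8
        assert drag_coefficient(re) * re / 24 == pytest.approx(1.0, rel=1e-6)

    def test_reference_values(self):
        assert drag_coefficient(1.0) == pytest.approx(27.6, abs=1e-6)
        assert drag_coefficient(1000.0) == pytest.approx(0.438, abs=5e-4)
        assert drag_coefficient(5000.0) == 0.44

    def test_negative_reynolds_rejected(self):
        with pytest.raises(ValueError):
            drag_coefficient(-1.0)


class TestParticleDynamics:
    def test_stokes_relaxation_time(self):
        """Slip decays as exp(-t/tau_p), tau_p = rho_p d^2 / (18 mu)."""
        d = 2e-3
        rho_p = 1080.0
        tau = rho_p * d**2 / (18 * BLOOD.viscosity)
        assert tau == pytest.approx(0.069, abs=1e-3)
        U = np.array([0.1, 0.0])

        def sampler(x, t):
            return np.tile(U, (len(x), 1))

        fm = ForceModel(drag="stokes", c_am=0.0, pressure_gradient=False)
        batch = _Batch(np.zeros((1, 2)), np.zeros((1, 2)), np.array([d]),
                       rho_p, fm, BLOOD)
        dt = tau / 100
        t = 0.0
        for _ in range(300):  # 3 tau
            batch.step(t, dt, sampler)
            t += dt
            slip = np.linalg.norm(U - batch.v[0])
            assert abs(slip - 0.1 * np.exp(-t / tau)) < 0.01 * 0.1

    def test_drag_vanishes_at_zero_slip(self):
        """A clot moving with the fluid feels no drag acceleration."""
        fm = ForceModel(c_am=0.0, pressure_gradient=False)
        U = np.array([0.3, 0.1])

        def sampler(x, t):
            return np.tile(U, (len(x), 1))

        batch = _Batch(np.zeros((1, 2)), U[None, :].copy(), np.array([4e-3]),
                       1080.0, fm, BLOOD)
        batch.step(0.0, 1e-3, sampler)
        np.testing.assert_allclose(batch.v[0], U, atol=1e-14)

    def test_density_matched_tracer_conserves_orbit(self):
        """Neutrally buoyant clot in solid-body rotation keeps its radius."""
        om = 2.0

        def sampler(x, t):
            return np.stack([-om * x[:, 1], om * x[:, 0]], axis=1)

        r0 = 0.05
        batch = _Batch(
            np.array([[r0, 0.0]]), np.array([[0.0, om * r0]]),
            np.array([2e-3]), BLOOD.density, ForceModel(), BLOOD,
        )
        dt = 1e-3
        t = 0.0
        n = int(round(2 * np.pi / om / dt))
        for _ in range(n):
            batch.step(t, dt, sampler)
            t += dt
        r1 = np.linalg.norm(batch.x[0])
        assert abs(r1 - r0) / r0 < 0.01

    def test_advance_clot_wrapper(self, normal_history, arch_mask):
        from emboflow.flow_solver import FlowField

        uc, vc = normal_history.snapshot_field(10)
        ny, nx = arch_mask.shape
        f0 = FlowField(0.0, np.zeros((ny, nx + 1)), np.zeros((ny + 1, nx)),
                       np.zeros((ny, nx)), arch_mask)
        # cell-centered fields are derived; emulate via direct batch check
        clot = Clot(diameter=3e-3, position=np.array([0.0, 0.01]),
                    velocity=np.array([0.0, 0.1]))
        out = advance_clot(clot, f0, f0, 1e-3, ForceModel(), BLOOD)
        assert out.status == "in_transit"
        assert out.position[1] > clot.position[1] - 1e-12


class TestWallInteraction:
    @staticmethod
    def _halfspace():  # fluid y > 0, wall at y = 0
        def sdf(x):
            return -x[:, 1]

        def normal(x):
            n = np.zeros_like(x)
            n[:, 1] = -1.0
            return n

        return sdf, normal

    def test_head_on_contact_zeroes_normal_velocity(self):
        sdf, normal = self._halfspace()
        x, v = wall_interact([[0.0, 0.5e-3]], [[0.0, -0.1]], [1e-3], sdf, normal)
        assert x[0, 1] == pytest.approx(1e-3)
        assert v[0, 1] == 0.0

    def test_tangential_slide_preserved(self):
        sdf, normal = self._halfspace()
        x, v = wall_interact([[0.0, 0.5e-3]], [[0.2, -0.1]], [1e-3], sdf, normal)
        assert v[0, 0] == pytest.approx(0.2)
        assert v[0, 1] == 0.0

    def test_no_contact_no_change(self):
        sdf, normal = self._halfspace()
        x, v = wall_interact([[0.0, 5e-3]], [[0.0, -0.1]], [1e-3], sdf, normal)
        assert x[0, 1] == pytest.approx(5e-3)
        assert v[0, 1] == pytest.approx(-0.1)

    def test_corner_zeroes_both_normals(self):
        # fluid quadrant x>0, y>0 (box corner at origin)
        def sdf(x):
            return np.maximum(-x[:, 0], -x[:, 1])

        def normal(x):
            n = np.where(
                (-x[:, 0] > -x[:, 1])[:, None],
                np.array([-1.0, 0.0]),
                np.array([0.0, -1.0]),
            )
            return n

        x, v = wall_interact([[0.2e-3, 0.3e-3]], [[-0.1, -0.2]], [1e-3], sdf, normal)
        assert x[0, 0] >= 1e-3 - 1e-9
        assert x[0, 1] >= 1e-3 - 1e-9
        np.testing.assert_allclose(v[0], [0.0, 0.0], atol=1e-12)


class TestOutcomes:
    def test_classify_synthetic_paths(self, case1_geometry):
        g = case1_geometry
        cx, cy = g.bend_center
        ex, ey = g.branch_axis(1)
        in_lcca = [cx + (g.branch_port_radius(1) + 2e-3) * ex,
                   cy + (g.branch_port_radius(1) + 2e-3) * ey]
        below_desc = [g.desc_center_x, -2e-3]
        inside = [0.0, 0.01]
        st = classify_outcome(np.array([in_lcca, below_desc, inside]), g)
        assert st == ["exited_LCCA", "exited_desc", "in_transit"]

    def test_every_clot_gets_exactly_one_terminal_status(
        self, normal_history, case1_geometry, normal_condition
    ):
        g = case1_geometry
        R = g.D_AA / 2
        xs = np.linspace(-0.4 * R, 0.4 * R, 17)
        pos = np.column_stack([xs, np.full(17, 0.1 * g.D_AA)])
        vel = np.column_stack([np.zeros(17), np.full(17, 0.74)])
        t0 = ejection_times(normal_condition.waveform)[2]
        statuses, exit_times, _, _ = simulate_clots(
            normal_history.sample_velocity, g, pos, vel, np.full(17, 3e-3),
            t0=t0, t_max=t0 + 3.0, dt=1e-3, blood=BLOOD,
        )
        from emboflow.clot_transport import TERMINAL_STATUSES

        assert all(s in TERMINAL_STATUSES for s in statuses)
        assert len(statuses) == 17
        exited = np.array([s.startswith("exited") for s in statuses])
        assert np.isfinite(exit_times[exited]).all()

    def test_timestep_halving_rarely_changes_exit_branch(
        self, normal_history, case1_geometry, normal_condition
    ):
        """Halving the particle step flips the exit branch on <5% of probes."""
        g = case1_geometry
        R = g.D_AA / 2
        n = 50
        xs = np.linspace(-0.4 * R, 0.4 * R, n)
        pos = np.column_stack([xs, np.full(n, 0.1 * g.D_AA)])
        vel = np.column_stack([np.zeros(n), np.full(n, 0.74)])
        dia = np.full(n, 4e-3)
        t0 = ejection_times(normal_condition.waveform)[2]
        horizon = 5 * normal_condition.waveform.T
        outs = []
        for dt in (1e-3, 5e-4):
            statuses, _, _, _ = simulate_clots(
                normal_history.sample_velocity, g, pos, vel, dia,
                t0=t0, t_max=t0 + horizon, dt=dt, blood=BLOOD,
            )
            outs.append(np.asarray(statuses))
        flips = (outs[0] != outs[1]).mean()
        assert flips < 0.05

    def test_tracer_matches_streamline_integration(
        self, normal_history, case1_geometry, normal_condition
    ):
        """Vanishing-size neutrally buoyant clots follow streamlines (>=90%)."""
        g = case1_geometry
        R = g.D_AA / 2
        n = 50
        xs = np.linspace(-0.4 * R, 0.4 * R, n)
        pos = np.column_stack([xs, np.full(n, 0.1 * g.D_AA)])
        t0 = ejection_times(normal_condition.waveform)[2]
        u0 = normal_history.sample_velocity(pos, t0)
        statuses, _, _, _ = simulate_clots(
            normal_history.sample_velocity, g, pos, u0, np.full(n, 1e-4),
            t0=t0, t_max=t0 + 3.0, dt=5e-4, blood=BLOOD,
            density=BLOOD.density,
        )
        # independent streamline (pathline) integration: midpoint rule
        x = pos.copy()
        done = np.array([""] * n, dtype=object)
        t = t0
        dt = 5e-4
        for _ in range(int(3.0 / dt)):
            active = done == ""
            if not active.any():
                break
            u1 = normal_history.sample_velocity(x[active], t)
            xm = x[active] + 0.5 * dt * u1
            u2 = normal_history.sample_velocity(xm, t + 0.5 * dt)
            x[active] = x[active] + dt * u2
            codes = g.port_status(x[active])
            from emboflow.clot_transport import STATUS_BY_LABEL

            idx = np.nonzero(active)[0]
            for loc in np.nonzero(codes != 0)[0]:
                done[idx[loc]] = STATUS_BY_LABEL[int(codes[loc])]
            t += dt
        done[done == ""] = "retained"
        agree = (np.asarray(statuses) == done).mean()
        assert agree >= 0.90


class TestTwoWayCoupling:
    def test_momentum_feedback_stable_and_close_to_one_way(self):
        """The particle-source-in-cell toggle stays stable and only mildly
        perturbs a single clot's path in a steady channel."""
        from emboflow.clot_transport import run_two_way
        from emboflow.flow_solver import ProjectionSolver, SolverConfig
        from emboflow.geometry import channel_mask
        from emboflow.hemodynamics import FlowWaveform

        H, U = 0.01, 0.05
        mask = channel_mask(H, 6 * H, H / 16)
        wf = FlowWaveform(
            label="c", T=1e9, T_s=1e8, U_peak=U,
            u=lambda t: np.full_like(np.asarray(t, dtype=float), U),
        )
        finals = {}
        for two_way in (False, True):
            solver = ProjectionSolver(
                mask, BLOOD, SolverConfig(outlet_fractions={"desc": 1.0}, dt=2e-3), wf
            )
            clot = Clot(diameter=2e-3, position=np.array([0.0, 0.01]),
                        velocity=np.array([0.0, U]))
            out = run_two_way(solver, clot, t_max=2.0,
                              force_model=ForceModel(two_way=two_way))
            assert np.linalg.norm(out.velocity) < 1.0  # no runaway
            finals[two_way] = out.position[1]
        assert finals[True] == pytest.approx(finals[False], rel=0.1)
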