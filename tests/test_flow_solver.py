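"""Flow-solver physics: Poiseuille, Womersley, mass balance, WSS."""

import math

import numpy as np
import pytest

from emboflow.flow_solver import (
    ProjectionSolver,
    SolverConfig,
    compute_wss,
    run_cycles,
    step_flow,
)
from emboflow.geometry import channel_mask
from emboflow.hemodynamics import BloodProperties, FlowWaveform, make_condition

BLOOD = BloodProperties()
NU = BLOOD.nu


def constant_waveform(U):
    return FlowWaveform(
        label="const", T=1e9, T_s=1e8, U_peak=U,
        u=lambda t: np.full_like(np.asarray(t, dtype=float), U),
    )


def run_channel(n_across, length_widths=12, t_end=9.0, Re=100.0, H=0.01):
    """Drive a straight channel to steady state at the given Reynolds number."""
    U = Re * NU / H
    h = H / n_across
    mask = channel_mask(H, length_widths * H, h)
    cfg = SolverConfig(outlet_fractions={"desc": 1.0})
    solver = ProjectionSolver(mask, BLOOD, cfg, constant_waveform(U))
    dt = min(0.4 * h / (1.6 * U), h * h / (6 * NU))
    for _ in range(int(t_end / dt)):
        solver.step(dt)
    return solver, mask, U, H


@pytest.fixture(scope="module")
def poiseuille():
    solver, mask, U, H = run_channel(32)
    return solver, mask, U, H


class TestPoiseuille:
    def test_centerline_to_mean_ratio(self, poiseuille):
        """Developed plane Poiseuille flow has u_max / u_mean = 1.5."""
        solver, mask, U, H = poiseuille
        f = solver.field()
        j = int(round((8 * H - mask.origin[1]) / mask.spacing - 0.5))
        prof = f.vc[j, mask.fluid[j]]
        ratio = prof.max() / prof.mean()
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_wall_shear_stress(self, poiseuille):
        """tau_w = 6 mu U / h for plane Poiseuille at mean velocity U."""
        solver, mask, U, H = poiseuille
        f = solver.field()
        j = int(round((8 * H - mask.origin[1]) / mask.spacing - 0.5))
        u_mean = f.vc[j, mask.fluid[j]].mean()
        wss = compute_wss(f, mask, BLOOD)
        sel = (wss["y"] > 6 * H) & (wss["y"] < 10 * H)
        tau = wss["tau"][sel].mean()
        assert tau == pytest.approx(6 * BLOOD.viscosity * u_mean / H, rel=0.05)

    def test_mass_conservation_each_step(self, poiseuille):
        solver, _, _, _ = poiseuille
        assert solver.last_mass_err <= 5e-3

    def test_wss_error_decreases_with_refinement(self):
        # Re=50 keeps the development length (~2.5 widths) well upstream of
        # the measurement window so discretization error dominates
        errs = []
        for n in (8, 16):
            solver, mask, U, H = run_channel(n, length_widths=10, t_end=12.0,
                                             Re=50)
            f = solver.field()
            j = int(round((8 * H - mask.origin[1]) / mask.spacing - 0.5))
            u_mean = f.vc[j, mask.fluid[j]].mean()
            wss = compute_wss(f, mask, BLOOD)
            sel = (wss["y"] > 7 * H) & (wss["y"] < 9 * H)
            tau = wss["tau"][sel].mean()
            exact = 6 * BLOOD.viscosity * u_mean / H
            errs.append(abs(tau - exact) / exact)
        assert errs[1] < errs[0]


class TestWomersley:
    def test_oscillatory_profile_matches_closed_form(self):
        """Body-force-driven channel at alpha=5 vs the analytic solution.

        The channel is periodic along the flow; the solver is initialized
        from the closed-form profile and integrated for two periods.  The
        profile L2 error (normalized by the cycle-peak analytic norm) stays
        within 5%.
        """
        H = 0.01
        alpha = 5.0
        om = (2 * alpha / H) ** 2 * NU
        T = 2 * math.pi / om
        h = H / 32
        mask = channel_mask(H, 8 * h, h, periodic=True)
        G0 = 0.01 * om

        def bf(t):
            return (0.0, G0 * math.cos(om * t))

        cfg = SolverConfig(outlet_fractions={"desc": 1.0})
        solver = ProjectionSolver(mask, BLOOD, cfg, waveform=None, body_force=bf)

        a = H / 2
        k = np.sqrt(1j * om / NU)
        xc, _ = mask.cell_centers()
        cols = np.nonzero(mask.fluid[0])[0]
        yy = xc[cols]

        def analytic(t):
            prof = (G0 / (1j * om)) * (1 - np.cosh(k * yy) / np.cosh(k * a))
            return (prof * np.exp(1j * om * t)).real

        peak_norm = max(
            np.linalg.norm(analytic(t)) for t in np.linspace(0, T, 50)
        )
        for j in range(mask.labels.shape[0] + 1):
            solver.v[j, cols] = analytic(0.0)
        dt = min(h * h / (6 * NU), T / 400)
        nsteps = int(round(2 * T / dt))
        dt = 2 * T / nsteps
        errs = []
        for i in range(nsteps):
            solver.step(dt)
            if i > nsteps // 2 and i % 40 == 0:
                num = solver.field().vc[3, cols]
                errs.append(np.linalg.norm(num - analytic(solver.t)) / peak_norm)
        assert max(errs) < 0.05


class TestStepFlow:
    def test_zero_inlet_stays_zero(self):
        mask = channel_mask(0.01, 0.04, 0.01 / 8)
        cfg = SolverConfig(outlet_fractions={"desc": 1.0})
        from emboflow.flow_solver import FlowField

        f = FlowField(
            0.0,
            np.zeros((mask.shape[0], mask.shape[1] + 1)),
            np.zeros((mask.shape[0] + 1, mask.shape[1])),
            np.zeros(mask.shape),
            mask,
        )
        f2 = step_flow(f, 1e-3, constant_waveform(0.0), mask, cfg)
        assert np.abs(f2.u).max() == 0.0
        assert np.abs(f2.v).max() == 0.0

    def test_divergence_tolerance_after_projection(self, normal_history):
        # recorded arch run kept mass balanced and divergence-free
        assert normal_history.max_mass_err <= 5e-3


class TestRunCycles:
    def test_periodicity_diagnostic_decreases(self, af_history):
        """Cycle-to-cycle L2 change decays as the startup transient washes out."""
        diag = af_history.periodicity
        assert len(diag) >= 2
        assert diag[-1] < diag[0]

    def test_zero_or_one_cycles_rejected(self, af_condition):
        mask = channel_mask(0.01, 0.04, 0.01 / 8)
        with pytest.raises(ValueError):
            run_cycles(af_condition, mask, SolverConfig(outlet_fractions={"desc": 1.0}),
                       n_cycles=0)

    def test_determinism_bit_identical(self):
        cond = make_condition("af", D=0.01, CO_target=0.4)
        mask = channel_mask(0.01, 0.03, 0.01 / 8)
        cfg = SolverConfig(outlet_fractions={"desc": 1.0}, snapshots_per_cycle=10)
        h1 = run_cycles(cond, mask, cfg, n_cycles=2)
        h2 = run_cycles(cond, mask, cfg, n_cycles=2)
        assert np.array_equal(h1.uc, h2.uc)
        assert np.array_equal(h1.vc, h2.vc)


class TestWss:
    def test_zero_field_zero_stress(self, arch_mask):
        uc = np.zeros(arch_mask.shape)
        vc = np.zeros(arch_mask.shape)
        wss = compute_wss((uc, vc), arch_mask, BLOOD)
        assert len(wss) > 0
        assert np.abs(wss["tau"]).max() == 0.0

    def test_arch_wss_higher_under_normal_rhythm(
        self, normal_history, af_history, blood
    ):
        """Cycle-peak spatial-mean WSS: normal exceeds AF on the same grid."""
        from emboflow.flow_solver import cycle_peak_mean_wss

        tau_n = cycle_peak_mean_wss(normal_history, blood)
        tau_af = cycle_peak_mean_wss(af_history, blood)
        assert tau_n > tau_af > 0


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SolverConfig(outlet_fractions={"BCA": 0.2, "LCCA": 0.2, "LSA": 0.2,
                                           "desc": 0.3})

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(outlet_fractions={"desc": 1.5, "BCA": -0.5})

    def test_fraction_port_coverage_checked(self):
        # channel has only a descending outlet; arch fractions don't cover it
        mask = channel_mask(0.01, 0.03, 0.01 / 8)
        with pytest.raises(ValueError):
            ProjectionSolver(mask, BLOOD, SolverConfig(), constant_waveform(0.1))
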