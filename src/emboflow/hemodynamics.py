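"""Inlet waveforms and dimensionless hemodynamic characterization.

Normal and atrial-fibrillation (AF) inlet conditions are generated from a
half-sine systolic pulse: velocity ``U_peak * sin(pi t / T_s)`` during
systole and zero flow in diastole.  The systolic duration ``T_s`` is solved
from the target cardiac output, so each generated waveform satisfies the
printed constraints simultaneously: cycle length (1 s normal, 0.6 s AF),
cardiac output (5.5 L/min normal, 30% less in AF), and peak velocity
(0.74 m/s normal, 0.32 m/s AF).

Blood is treated as Newtonian with density 1060 kg/m^3 and dynamic
viscosity 3.5e-3 Pa s (kinematic viscosity 3.30e-6 m^2/s) — the single
property set that reconciles the four printed dimensionless numbers
(Womersley 20 and 25.8; peak Reynolds 6500 at 0.74 m/s and D = 29 mm;
cycle-mean Reynolds about 1200 at 5.5 L/min).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "BloodProperties",
    "FlowWaveform",
    "HemodynamicCondition",
    "make_waveform",
    "make_condition",
    "womersley",
    "reynolds",
    "ejection_times",
    "NORMAL_DEFAULTS",
    "AF_DEFAULTS",
]

#: printed study conditions for the two inlet waveforms
NORMAL_DEFAULTS = {"T": 1.0, "CO_l_min": 5.5, "U_peak": 0.74, "D": 29.0e-3}
AF_DEFAULTS = {"T": 0.6, "CO_l_min": 0.7 * 5.5, "U_peak": 0.32, "D": 29.0e-3}


class WaveformError(ValueError):
    """Raised when the requested waveform constraints are infeasible."""


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1060.0
    viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood properties must be strictly positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity mu/rho (m^2/s)."""
        return self.viscosity / self.density


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic inlet velocity profile u(t)."""

    label: str
    T: float
    T_s: float
    U_peak: float
    u: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if not (0 < self.T_s < self.T):
            raise WaveformError("systolic duration must satisfy 0 < T_s < T")
        peak = float(np.max(self.u(np.linspace(0, self.T, 20001))))
        if abs(peak - self.U_peak) > 1e-3 * self.U_peak:
            raise WaveformError("stored U_peak does not match max of u(t)")

    def mean_velocity(self, n: int = 20001) -> float:
        """Cycle-mean of u(t) by trapezoidal quadrature."""
        t = np.linspace(0.0, self.T, n)
        return float(np.trapezoid(self.u(t), t) / self.T)

    def cardiac_output(self, D: float) -> float:
        """CO in L/min through a circular inlet of diameter ``D`` (m)."""
        area = math.pi * D**2 / 4
        return self.mean_velocity() * area * 60.0 * 1000.0

    def to_csv(self, path, n: int = 501) -> None:
        t = np.linspace(0.0, self.T, n)
        arr = np.column_stack([t, self.u(t)])
        np.savetxt(path, arr, delimiter=",", header="time_s,velocity_m_s", comments="")


def _half_sine(U_peak: float, T: float, T_s: float) -> Callable:
    def u(t):
        t = np.asarray(t, dtype=float) % T
        return np.where(t <= T_s, U_peak * np.sin(np.pi * np.minimum(t, T_s) / T_s), 0.0)

    return u


def make_waveform(
    label: str,
    T: float | None = None,
    CO_target: float | None = None,
    U_peak_target: float | None = None,
    D: float | None = None,
) -> FlowWaveform:
    """Generate a half-sine inlet waveform meeting the printed constraints.

    Parameters default to the study conditions for ``label`` ("normal" or
    "af").  ``CO_target`` is in L/min; the generated waveform's cycle-mean
    velocity times the circular inlet area reproduces it to better than
    0.5%, and its maximum equals ``U_peak_target``.
    """
    defaults = {"normal": NORMAL_DEFAULTS, "af": AF_DEFAULTS}.get(label.lower())
    if defaults is None:
        defaults = NORMAL_DEFAULTS  # custom label: normal-shaped family
    T = float(T if T is not None else defaults["T"])
    CO = float(CO_target if CO_target is not None else defaults["CO_l_min"])
    U_peak = float(U_peak_target if U_peak_target is not None else defaults["U_peak"])
    D = float(D if D is not None else defaults["D"])
    if min(T, CO, U_peak, D) <= 0:
        raise WaveformError("all waveform parameters must be positive")
    area = math.pi * D**2 / 4
    u_mean = CO / 60.0 / 1000.0 / area
    # half-sine mean over the cycle: (2/pi) U_peak T_s / T
    T_s = u_mean * T * math.pi / (2 * U_peak)
    if T_s >= T:
        raise WaveformError(
            f"infeasible constraints: required systolic duration {T_s:.3f} s "
            f">= cycle length {T:.3f} s (need mean velocity < (2/pi) U_peak)"
        )
    return FlowWaveform(label=label, T=T, T_s=T_s, U_peak=U_peak, u=_half_sine(U_peak, T, T_s))


def womersley(D: float, T: float, nu: float) -> float:
    """Womersley number ``(D/2) sqrt(2 pi / (T nu))``."""
    if min(D, T, nu) <= 0:
        raise ValueError("womersley arguments must be positive")
    return (D / 2) * math.sqrt(2 * math.pi / (T * nu))


def reynolds(U: float, D: float, nu: float) -> float:
    """Reynolds number ``U D / nu``."""
    if D <= 0 or nu <= 0:
        raise ValueError("D and nu must be positive")
    if U < 0:
        raise ValueError("U must be non-negative")
    return U * D / nu


def ejection_times(waveform: FlowWaveform, n: int = 20001) -> tuple[float, float, float]:
    """Clot-ejection moments: systole onset, accelerating stage, peak flow.

    The accelerating moment is the first upstroke crossing of ``U_peak/2``;
    the peak moment is the argmax of u over one cycle.  For the half-sine
    family these are ``0``, ``T_s/6`` and ``T_s/2``.
    """
    t = np.linspace(0.0, waveform.T, n)
    u = waveform.u(t)
    i_peak = int(np.argmax(u))
    t_peak = float(t[i_peak])
    nonzero = np.nonzero(u > 1e-9 * waveform.U_peak)[0]
    if len(nonzero) == 0:
        raise WaveformError("waveform has no systolic pulse")
    i_begin = max(int(nonzero[0]) - 1, 0)
    t_begin = float(t[i_begin])
    up = np.nonzero(u[: i_peak + 1] >= waveform.U_peak / 2)[0]
    if len(up) == 0:
        raise WaveformError("non-unimodal systolic pulse: no half-peak upstroke")
    i = int(up[0])
    # linear interpolation of the crossing
    if i > 0 and u[i] > u[i - 1]:
        frac = (waveform.U_peak / 2 - u[i - 1]) / (u[i] - u[i - 1])
        t_accel = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    else:
        t_accel = float(t[i])
    if not (t_begin < t_accel < t_peak):
        raise WaveformError("ejection moments not ordered; pulse not unimodal")
    return t_begin, t_accel, t_peak


@dataclass(frozen=True)
class HemodynamicCondition:
    """Waveform plus blood and inlet geometry with derived dimensionless groups."""

    waveform: FlowWaveform
    blood: BloodProperties
    D: float
    CO_l_min: float
    alpha: float
    Re_peak: float
    Re_mean: float

    @property
    def label(self) -> str:
        return self.waveform.label

    def verify(self, rtol: float = 5e-3) -> None:
        """Recompute CO, alpha, Re from u(t), D, nu and compare to stored fields."""
        co = self.waveform.cardiac_output(self.D)
        al = womersley(self.D, self.waveform.T, self.blood.nu)
        rp = reynolds(self.waveform.U_peak, self.D, self.blood.nu)
        rm = reynolds(self.waveform.mean_velocity(), self.D, self.blood.nu)
        for stored, fresh, name in [
            (self.CO_l_min, co, "CO"),
            (self.alpha, al, "alpha"),
            (self.Re_peak, rp, "Re_peak"),
            (self.Re_mean, rm, "Re_mean"),
        ]:
            if abs(stored - fresh) > rtol * abs(fresh):
                raise ValueError(f"self-consistency failure for {name}: {stored} vs {fresh}")

    def summary(self) -> dict:
        return {
            "label": self.label,
            "cycle_length_s": self.waveform.T,
            "systolic_duration_s": self.waveform.T_s,
            "U_peak_m_s": self.waveform.U_peak,
            "U_mean_m_s": self.waveform.mean_velocity(),
            "D_m": self.D,
            "CO_l_min": self.CO_l_min,
            "womersley": self.alpha,
            "Re_peak": self.Re_peak,
            "Re_mean": self.Re_mean,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def make_condition(
    label: str,
    blood: BloodProperties | None = None,
    **waveform_kwargs,
) -> HemodynamicCondition:
    """Build a fully characterized hemodynamic condition ("normal" or "af")."""
    blood = blood or BloodProperties()
    wf = make_waveform(label, **waveform_kwargs)
    D = float(waveform_kwargs.get("D") or
              {"normal": NORMAL_DEFAULTS, "af": AF_DEFAULTS}.get(label.lower(), NORMAL_DEFAULTS)["D"])
    cond = HemodynamicCondition(
        waveform=wf,
        blood=blood,
        D=D,
        CO_l_min=wf.cardiac_output(D),
        alpha=womersley(D, wf.T, blood.nu),
        Re_peak=reynolds(wf.U_peak, D, blood.nu),
        Re_mean=reynolds(wf.mean_velocity(), D, blood.nu),
    )
    cond.verify()
    return cond
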