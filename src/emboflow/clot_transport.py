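"""Lagrangian transport of spherical emboli through a time-varying flow.

Each clot is a point particle with a finite collision radius, advanced by a
midpoint (RK2) integration of Newton's second law with a standard
discrete-phase force set:

* drag — Schiller-Naumann correlation (Stokes drag as the low-Reynolds
  limit, constant C_d = 0.44 above particle Reynolds 1000),
* pressure-gradient (fluid-acceleration) force,
* added mass with coefficient ``C_am = 0.5``,
* optional gravity/buoyancy (off by default; the arch orientation relative
  to gravity is a free choice of the planar reduction).

The carrier velocity is interpolated bilinearly at the clot center; the
fluid acceleration is estimated by differencing the sampled velocity along
the local fluid path.  Wall contact projects the center back to a
half-diameter standoff and zeroes the wall-normal velocity (free slide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    ArchGeometry,
    DomainMask,
    INLET,
    OUTLET_BCA,
    OUTLET_DESC,
    OUTLET_LCCA,
    OUTLET_LSA,
)
from .hemodynamics import BloodProperties

__all__ = [
    "Clot",
    "ForceModel",
    "TrajectoryRecord",
    "drag_coefficient",
    "advance_clot",
    "wall_interact",
    "classify_outcome",
    "simulate_clots",
    "STATUS_BY_LABEL",
    "TERMINAL_STATUSES",
]

IN_TRANSIT = "in_transit"
STATUS_BY_LABEL = {
    OUTLET_BCA: "exited_BCA",
    OUTLET_LCCA: "exited_LCCA",
    OUTLET_LSA: "exited_LSA",
    OUTLET_DESC: "exited_desc",
    INLET: "retained",  # backflow out of the inlet counts as non-embolizing
}
TERMINAL_STATUSES = ("exited_BCA", "exited_LCCA", "exited_LSA", "exited_desc", "retained")


@dataclass
class Clot:
    """A discrete spherical embolus."""

    diameter: float
    density: float = 1080.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    status: str = IN_TRANSIT

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("clot diameter and density must be positive")


@dataclass(frozen=True)
class ForceModel:
    """Force terms acting on a clot.

    ``drag`` selects the correlation ("schiller_naumann" or "stokes");
    ``two_way`` enables particle-source-in-cell momentum feedback in the
    coupled stepper (one-way frozen-field transport ignores it).
    """

    drag: str = "schiller_naumann"
    c_am: float = 0.5
    pressure_gradient: bool = True
    gravity: bool = False
    g: tuple[float, float] = (0.0, -9.81)
    two_way: bool = False

    def __post_init__(self) -> None:
        if self.c_am < 0:
            raise ValueError("added-mass coefficient must be >= 0")
        if self.drag not in ("schiller_naumann", "stokes"):
            raise ValueError("drag must be 'schiller_naumann' or 'stokes'")


@dataclass
class TrajectoryRecord:
    """Sampled path of one clot from release to its terminal outcome."""

    release: dict
    times: np.ndarray
    positions: np.ndarray
    status: str
    exit_time: float | None

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.positions])
        np.savetxt(path, arr, delimiter=",", header="t,x,y", comments="")


def drag_coefficient(re_p):
    """Schiller-Naumann drag coefficient.

    ``C_d = (24/Re)(1 + 0.15 Re^0.687)`` for ``0 < Re <= 1000`` and 0.44
    above; tends to the Stokes law 24/Re as ``Re -> 0``.
    """
    re = np.asarray(re_p, dtype=float)
    if np.any(re < 0):
        raise ValueError("particle Reynolds number must be non-negative")
    with np.errstate(divide="ignore"):
        cd = np.where(
            re > 1000.0,
            0.44,
            24.0 / re * (1.0 + 0.15 * re**0.687),
        )
    return cd if cd.ndim else float(cd)


def _drag_factor(rel_speed, d, blood: BloodProperties, model: ForceModel):
    """phi = C_d Re_p / 24 (the Stokes-drag multiplier), singularity-free."""
    if model.drag == "stokes":
        return np.ones_like(np.asarray(rel_speed, dtype=float))
    re = np.asarray(rel_speed, dtype=float) * d / blood.nu
    phi = 1.0 + 0.15 * np.minimum(re, 1000.0) ** 0.687
    return np.where(re > 1000.0, 0.44 * re / 24.0, phi)


class _Batch:
    """Vectorized state of N simultaneously advancing clots."""

    def __init__(self, positions, velocities, diameters, density, model, blood):
        self.x = np.array(positions, dtype=float)
        self.v = np.array(velocities, dtype=float)
        self.d = np.asarray(diameters, dtype=float)
        self.rho_p = float(density)
        self.model = model
        self.blood = blood
        rho_f = blood.density
        self.inertia = self.rho_p + model.c_am * rho_f
        self.accel_coef = rho_f * ((1.0 if model.pressure_gradient else 0.0) + model.c_am)
        self.accel_coef /= self.inertia

    def _coefficients(self, x, v, t, sampler, dt_fd):
        """Drag rate ``k`` and drift velocity ``v_inf`` of the linearized
        equation of motion ``v' = k (v_inf - v)`` at the given state."""
        uf = sampler(x, t)
        if self.accel_coef != 0.0:
            uf2 = sampler(x + uf * dt_fd, t + dt_fd)
            af = (uf2 - uf) / dt_fd
        else:
            af = np.zeros_like(uf)
        rel = uf - v
        speed = np.linalg.norm(rel, axis=1)
        phi = _drag_factor(speed, self.d, self.blood, self.model)
        k = 18.0 * self.blood.viscosity * phi / (self.d**2 * self.inertia)
        extra = self.accel_coef * af
        if self.model.gravity:
            extra = extra + (self.rho_p - self.blood.density) / self.inertia * np.asarray(
                self.model.g
            )
        v_inf = uf + extra / k[:, None]
        return k, v_inf

    @staticmethod
    def _exp_update(x, v, k, v_inf, dtau):
        """Exact integration of ``v' = k (v_inf - v)`` over ``dtau``
        (unconditionally stable in the stiff-drag / tracer limit)."""
        e = np.exp(-k * dtau)[:, None]
        w = (-np.expm1(-k * dtau) / k)[:, None]  # (1 - e) / k, stable as k->0
        x_new = x + v_inf * dtau + (v - v_inf) * w
        v_new = v_inf + (v - v_inf) * e
        return x_new, v_new

    def step(self, t, dt, sampler, dt_fd: float = 1.0e-3):
        """One midpoint step with exponential (integrating-factor) drag.

        ``dt_fd`` is the finite-difference interval for the fluid
        acceleration estimate; it is fixed (independent of ``dt``) so the
        sampled force field does not change with the integration step.
        """
        k1, vinf1 = self._coefficients(self.x, self.v, t, sampler, dt_fd)
        xm, vm = self._exp_update(self.x, self.v, k1, vinf1, 0.5 * dt)
        k2, vinf2 = self._coefficients(xm, vm, t + 0.5 * dt, sampler, dt_fd)
        self.x, self.v = self._exp_update(self.x, self.v, k2, vinf2, dt)


def advance_clot(
    clot: Clot,
    field_t,
    field_t_dt,
    dt: float,
    force_model: ForceModel,
    blood: BloodProperties,
) -> Clot:
    """Advance a single in-transit clot by one step.

    ``field_t`` and ``field_t_dt`` are :class:`~emboflow.flow_solver.FlowField`
    snapshots at the current time and one step ahead; the carrier velocity
    is interpolated bilinearly in space and linearly in time between them.
    """
    if clot.status != IN_TRANSIT:
        raise ValueError("clot is not in transit")
    from .flow_solver import _bilinear

    mask = field_t.mask
    h = mask.spacing
    uc0, vc0 = field_t.uc, field_t.vc
    uc1, vc1 = field_t_dt.uc, field_t_dt.vc
    t0 = field_t.t

    def sampler(points, t):
        w = np.clip((t - t0) / dt, 0.0, 1.0)
        gx = (points[:, 0] - mask.origin[0]) / h - 0.5
        gy = (points[:, 1] - mask.origin[1]) / h - 0.5
        u = (1 - w) * _bilinear(uc0, gx, gy) + w * _bilinear(uc1, gx, gy)
        v = (1 - w) * _bilinear(vc0, gx, gy) + w * _bilinear(vc1, gx, gy)
        return np.stack([u, v], axis=1)

    batch = _Batch(
        clot.position[None, :], clot.velocity[None, :], np.array([clot.diameter]),
        clot.density, force_model, blood,
    )
    batch.step(t0, dt, sampler)
    return replace(clot, position=batch.x[0], velocity=batch.v[0])


def wall_interact(positions, velocities, radii, sdf, normal, n_iter: int = 3):
    """Project clot centers to a half-diameter wall standoff (vectorized).

    ``sdf``/``normal`` evaluate the signed distance (negative inside the
    fluid) and its outward gradient.  The normal velocity component is
    zeroed when directed into the wall; tangential motion is retained.
    Repeated projection resolves corners (both offending normals zeroed).
    """
    x = np.array(positions, dtype=float)
    v = np.array(velocities, dtype=float)
    r = np.asarray(radii, dtype=float)
    for _ in range(n_iter):
        d = np.asarray(sdf(x))
        bad = d > -r
        if not bad.any():
            break
        n = normal(x[bad])
        x[bad] -= (d[bad] + r[bad])[:, None] * n
        vn = np.sum(v[bad] * n, axis=1)
        push = vn > 0  # moving toward the wall
        corr = np.where(push, vn, 0.0)
        v[bad] -= corr[:, None] * n
    return x, v


def classify_outcome(positions, geometry: ArchGeometry, tol: float = 0.0):
    """Port-plane classification of clot centers.

    Returns a list of status strings; positions inside the domain map to
    ``in_transit``.
    """
    codes = geometry.port_status(positions, tol=tol)
    return [STATUS_BY_LABEL.get(int(c), IN_TRANSIT) for c in codes]


def _domain_tools(domain, mask: DomainMask | None):
    """(sdf, normal, port_status) callables for an arch or a plain mask."""
    if isinstance(domain, ArchGeometry):
        ext = 0.5 * domain.D_AA

        def sdf(x):
            return domain.sdf(x, port_extension=ext)

        def normal(x):
            return domain.wall_normal(x, port_extension=ext)

        def status(x):
            return domain.port_status(x)

        return sdf, normal, status
    # mask-only domains (validation channels): EDT distance, desc exit at top
    m = domain if isinstance(domain, DomainMask) else mask

    def sdf(x):
        return m.signed_distance(x)

    def normal(x):
        eps = m.spacing / 4
        gx = (m.signed_distance(x + [eps, 0]) - m.signed_distance(x - [eps, 0])) / (2 * eps)
        gy = (m.signed_distance(x + [0, eps]) - m.signed_distance(x - [0, eps])) / (2 * eps)
        g = np.stack([gx, gy], axis=1)
        nrm = np.linalg.norm(g, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return g / nrm

    y_top = m.origin[1] + m.labels.shape[0] * m.spacing

    def status(x):
        out = np.zeros(len(x), dtype=int)
        out[x[:, 1] > y_top - 3 * m.spacing] = OUTLET_DESC
        out[x[:, 1] < m.origin[1] + 2 * m.spacing] = INLET
        return out

    return sdf, normal, status


def simulate_clots(
    sampler,
    domain,
    positions,
    velocities,
    diameters,
    t0: float,
    t_max: float,
    dt: float,
    force_model: ForceModel | None = None,
    blood: BloodProperties | None = None,
    density: float = 1080.0,
    mask: DomainMask | None = None,
    record_stride: int = 0,
):
    """Advance an ensemble of clots until exit or ``t_max``.

    ``sampler(points, t)`` returns carrier velocities (N, 2); ``domain`` is
    an :class:`ArchGeometry` (exact distance field and port planes) or a
    :class:`DomainMask`.  Returns ``(statuses, exit_times, final_positions,
    records)`` where ``records`` is a list of :class:`TrajectoryRecord` when
    ``record_stride > 0`` else ``None``.
    """
    force_model = force_model or ForceModel()
    blood = blood or BloodProperties()
    sdf, normal, port_status = _domain_tools(domain, mask)
    batch = _Batch(positions, velocities, diameters, density, force_model, blood)
    n = len(batch.x)
    statuses = np.array([IN_TRANSIT] * n, dtype=object)
    exit_times = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    radii = batch.d / 2

    recording = record_stride > 0
    traj_t: list[list[float]] = [[t0] for _ in range(n)] if recording else []
    traj_x: list[list[np.ndarray]] = [[batch.x[i].copy()] for i in range(n)] if recording else []

    t = t0
    step_i = 0
    n_steps = max(1, int(math.ceil((t_max - t0) / dt)))
    for step_i in range(n_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        sub = _Batch(
            batch.x[idx], batch.v[idx], batch.d[idx], density, force_model, blood
        )
        sub.step(t, dt, sampler)
        t_new = t + dt
        # port crossing first (exits), then wall standoff projection
        codes = port_status(sub.x)
        exited = codes != 0
        if exited.any():
            for loc in np.nonzero(exited)[0]:
                gi = idx[loc]
                statuses[gi] = STATUS_BY_LABEL[int(codes[loc])]
                exit_times[gi] = t_new
                active[gi] = False
        keep = ~exited
        if keep.any():
            xw, vw = wall_interact(sub.x[keep], sub.v[keep], radii[idx][keep], sdf, normal)
            sub.x[keep] = xw
            sub.v[keep] = vw
        batch.x[idx] = sub.x
        batch.v[idx] = sub.v
        if recording and (step_i + 1) % record_stride == 0:
            for gi in idx:
                traj_t[gi].append(t_new)
                traj_x[gi].append(batch.x[gi].copy())
        t = t_new
    statuses[active] = "retained"

    records = None
    if recording:
        records = [
            TrajectoryRecord(
                release={"index": i},
                times=np.array(traj_t[i]),
                positions=np.array(traj_x[i]),
                status=str(statuses[i]),
                exit_time=None if np.isnan(exit_times[i]) else float(exit_times[i]),
            )
            for i in range(n)
        ]
    return statuses, exit_times, batch.x.copy(), records


def run_two_way(
    solver,
    clot: Clot,
    t_max: float,
    force_model: ForceModel | None = None,
):
    """Coupled stepping of one clot with momentum feedback on the flow.

    A minimal particle-source-in-cell scheme: each flow step the clot is
    advanced through the current field (stable exponential-drag update) and
    the equal-and-opposite momentum change is deposited on the carrier with
    bilinear weights over the surrounding cells, spread over a fluid slab of
    thickness ``d_p`` (the planar reduction has no true third dimension).
    Depositing the bounded particle impulse — rather than an instantaneous
    force — keeps the explicit coupling stable.  A fidelity toggle, not a
    validated model.  Returns the clot with its terminal or final state.
    """
    force_model = force_model or ForceModel(two_way=True)
    blood = solver.blood
    mask = solver.mask
    h = mask.spacing
    geometry = mask.geometry
    sdf, normal, port_status = _domain_tools(geometry if geometry is not None else mask, mask)
    dt = solver.config.dt or solver.config.cfl * h / max(
        solver.waveform.U_peak if solver.waveform else 1.0, 1e-9
    )
    d = clot.diameter
    m_p = clot.density * math.pi * d**3 / 6
    batch = _Batch(
        clot.position[None, :], clot.velocity[None, :], np.array([d]),
        clot.density, force_model, blood,
    )
    from .flow_solver import _bilinear  # noqa: F401  (sampler below)

    while solver.t < t_max:
        f = solver.field()
        uc, vc = f.uc, f.vc

        def sampler(points, t, uc=uc, vc=vc):
            gx = (points[:, 0] - mask.origin[0]) / h - 0.5
            gy = (points[:, 1] - mask.origin[1]) / h - 0.5
            return np.stack([_bilinear(uc, gx, gy), _bilinear(vc, gx, gy)], axis=1)

        v_old = batch.v[0].copy()
        x_old = batch.x[0].copy()
        batch.step(solver.t, dt, sampler)
        su = np.zeros_like(solver.u)
        sv = np.zeros_like(solver.v)
        if force_model.two_way:
            impulse = -m_p * (batch.v[0] - v_old)  # reaction on the carrier
            slab_mass = blood.density * h * h * max(d, h)
            gx = (x_old[0] - mask.origin[0]) / h - 0.5
            gy = (x_old[1] - mask.origin[1]) / h - 0.5
            i0 = int(np.clip(math.floor(gx), 0, solver.nx - 2))
            j0 = int(np.clip(math.floor(gy), 0, solver.ny - 2))
            fx, fy = gx - i0, gy - j0
            for (jj, ii, w) in (
                (j0, i0, (1 - fx) * (1 - fy)),
                (j0, i0 + 1, fx * (1 - fy)),
                (j0 + 1, i0, (1 - fx) * fy),
                (j0 + 1, i0 + 1, fx * fy),
            ):
                su[jj, ii] += w * impulse[0] / (slab_mass * dt)
                sv[jj, ii] += w * impulse[1] / (slab_mass * dt)
        solver.step(dt, momentum_source=(su, sv))
        code = int(port_status(batch.x)[0])
        if code != 0:
            return replace(
                clot, position=batch.x[0], velocity=batch.v[0],
                status=STATUS_BY_LABEL[code],
            )
        xw, vw = wall_interact(batch.x, batch.v, np.array([d / 2]), sdf, normal)
        batch.x, batch.v = xw, vw
    return replace(clot, position=batch.x[0], velocity=batch.v[0], status="retained")
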