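"""Unsteady incompressible flow in a masked 2-D domain.

A finite-difference projection solver on a staggered (MAC) grid: first-order
upwind advection, explicit diffusion, and an exact pressure projection via a
prefactorized sparse Poisson solve.  Boundary conditions are a plug inlet
velocity from the driving waveform, no-slip walls (second-order ghost-cell
reflection for tangential components), and prescribed-flux plug outflow at
every outlet port with fluxes rescaled each step so discrete mass balance
holds exactly.

An optional constant-coefficient Smagorinsky eddy viscosity provides a
flow-model sensitivity toggle; the default is laminar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .geometry import (
    FLUID,
    INLET,
    WALL,
    OUTLET_BCA,
    OUTLET_DESC,
    OUTLET_LCCA,
    OUTLET_LSA,
    DomainMask,
)
from .hemodynamics import BloodProperties, FlowWaveform, HemodynamicCondition

__all__ = [
    "SolverConfig",
    "FlowField",
    "ProjectionSolver",
    "CycleHistory",
    "step_flow",
    "run_cycles",
    "compute_wss",
    "wall_segments",
    "SolverError",
]

OUTLET_ORDER = {"BCA": OUTLET_BCA, "LCCA": OUTLET_LCCA, "LSA": OUTLET_LSA, "desc": OUTLET_DESC}


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the flow solver.

    ``outlet_fractions`` are the fixed fractions of the instantaneous inlet
    flow rate leaving each outlet; they must be non-negative and sum to 1.
    ``grid_spacing`` is carried for drivers that rasterize geometry; the
    solver itself reads the spacing from the mask.
    """

    grid_spacing: float | None = None
    cfl: float = 0.4
    dt: float | None = None
    outlet_fractions: dict = field(
        default_factory=lambda: {"BCA": 0.15, "LCCA": 0.075, "LSA": 0.075, "desc": 0.70}
    )
    eddy_viscosity_model: str = "none"
    smagorinsky_coeff: float = 0.17
    div_tol: float = 1e-8
    n_cycles: int = 3
    snapshots_per_cycle: int = 100

    def __post_init__(self) -> None:
        fr = self.outlet_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("outlet_fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"outlet_fractions must sum to 1 (got {sum(fr.values()):.6g} "
                f"for {sorted(fr)})"
            )
        if self.eddy_viscosity_model not in ("none", "smagorinsky"):
            raise ValueError("eddy_viscosity_model must be 'none' or 'smagorinsky'")


@dataclass
class FlowField:
    """Discrete velocity/pressure state at time ``t`` on a staggered grid.

    ``u`` has shape (ny, nx+1) on x-normal faces, ``v`` (ny+1, nx) on
    y-normal faces, ``p`` (ny, nx) at cell centers (defined up to a
    constant).
    """

    t: float
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mask: DomainMask

    @property
    def uc(self) -> np.ndarray:
        """x-velocity averaged to cell centers."""
        return 0.5 * (self.u[:, :-1] + self.u[:, 1:])

    @property
    def vc(self) -> np.ndarray:
        """y-velocity averaged to cell centers."""
        return 0.5 * (self.v[:-1, :] + self.v[1:, :])

    def copy(self) -> "FlowField":
        return FlowField(self.t, self.u.copy(), self.v.copy(), self.p.copy(), self.mask)


def _bilinear(arr: np.ndarray, gx, gy):
    """Bilinear sample of a cell-centered array at fractional indices."""
    ny, nx = arr.shape
    gx = np.clip(np.asarray(gx, dtype=float), 0.0, nx - 1.0)
    gy = np.clip(np.asarray(gy, dtype=float), 0.0, ny - 1.0)
    i0 = np.clip(np.floor(gx).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(gy).astype(int), 0, ny - 2)
    fx = gx - i0
    fy = gy - j0
    return (
        arr[j0, i0] * (1 - fx) * (1 - fy)
        + arr[j0, i0 + 1] * fx * (1 - fy)
        + arr[j0 + 1, i0] * (1 - fx) * fy
        + arr[j0 + 1, i0 + 1] * fx * fy
    )


class ProjectionSolver:
    """Operator-split projection stepper bound to one mask and config."""

    def __init__(
        self,
        mask: DomainMask,
        blood: BloodProperties,
        config: SolverConfig,
        waveform: FlowWaveform | None = None,
        body_force=None,
    ):
        self.mask = mask
        self.blood = blood
        self.config = config
        self.waveform = waveform
        self.body_force = body_force
        self.h = mask.spacing
        self.periodic_y = mask.periodic_y
        ny, nx = mask.shape
        self.ny, self.nx = ny, nx

        ct = mask.labels
        ctp = np.pad(ct, 1, constant_values=WALL)
        # u faces (ny, nx+1): left cell ctp[j+1, i], right cell ctp[j+1, i+1]
        uL = ctp[1:-1, 0 : nx + 1]
        uR = ctp[1:-1, 1 : nx + 2]
        # v faces (ny+1, nx): bottom cell ctp[j, i+1], top cell ctp[j+1, i+1]
        vB = ctp[0 : ny + 1, 1:-1]
        vT = ctp[1 : ny + 2, 1:-1]
        if self.periodic_y:
            # top/bottom padding rows wrap instead of being walls
            vB = vB.copy()
            vT = vT.copy()
            vB[0] = ct[-1]
            vT[-1] = ct[0]

        self.u_interior = (uL == FLUID) & (uR == FLUID)
        self.v_interior = (vB == FLUID) & (vT == FLUID)

        self.port_faces = {}  # label -> dict(u_mask, v_mask, F_unit, axis)
        labels_present = [l for l in mask.port_axes]
        for label in labels_present:
            um = ((uL == FLUID) & (uR == label)) | ((uL == label) & (uR == FLUID))
            unx = np.where(uR == label, 1.0, -1.0)  # outward normal x-sign
            vm = ((vB == FLUID) & (vT == label)) | ((vB == label) & (vT == FLUID))
            vny = np.where(vT == label, 1.0, -1.0)
            ax, ay = mask.port_axes[label]
            f_unit = float((ax * unx * um).sum() + (ay * vny * vm).sum()) * self.h
            self.port_faces[label] = {
                "u_mask": um,
                "v_mask": vm,
                "u_n": unx,
                "v_n": vny,
                "axis": (ax, ay),
                "F_unit": f_unit,
            }
        self.inlet_faces = self.port_faces.pop(INLET, None)
        self.outlets = {
            name: self.port_faces[lab]
            for name, lab in OUTLET_ORDER.items()
            if lab in self.port_faces
        }
        if self.outlets:
            covered = sum(config.outlet_fractions.get(n, 0.0) for n in self.outlets)
            if abs(covered - 1.0) > 1e-9:
                raise ValueError(
                    f"outlet_fractions for ports present ({sorted(self.outlets)}) "
                    f"sum to {covered:.6g}, expected 1"
                )

        # active faces carry a boundary or interior value (walls are 0 at the face)
        u_wall = ((uL == FLUID) & (uR == WALL)) | ((uL == WALL) & (uR == FLUID))
        v_wall = ((vB == FLUID) & (vT == WALL)) | ((vB == WALL) & (vT == FLUID))
        u_port_any = np.zeros_like(self.u_interior)
        v_port_any = np.zeros_like(self.v_interior)
        for pf in ([self.inlet_faces] if self.inlet_faces else []) + list(self.outlets.values()):
            u_port_any |= pf["u_mask"]
            v_port_any |= pf["v_mask"]
        self.u_active = self.u_interior | u_wall | u_port_any
        self.v_active = self.v_interior | v_wall | v_port_any
        # ghost faces for tangential no-slip (reflection about the wall face)
        act = self.u_active
        self.u_ghost_dn = ~act & np.roll(act, -1, axis=0)
        self.u_ghost_up = ~act & np.roll(act, 1, axis=0) & ~self.u_ghost_dn
        act = self.v_active
        self.v_ghost_lt = ~act & np.roll(act, -1, axis=1)
        self.v_ghost_rt = ~act & np.roll(act, 1, axis=1) & ~self.v_ghost_lt

        self._build_poisson()

        self.u = np.zeros((ny, nx + 1))
        self.v = np.zeros((ny + 1, nx))
        self.p = np.zeros((ny, nx))
        self.t = 0.0
        self.last_div = 0.0
        self.last_mass_err = 0.0

    # ------------------------------------------------------------------ setup

    def _build_poisson(self) -> None:
        fluid = self.mask.fluid
        ny, nx = fluid.shape
        idx = -np.ones((ny, nx), dtype=int)
        nf = int(fluid.sum())
        idx[fluid] = np.arange(nf)
        rows, cols, vals = [], [], []
        diag = np.zeros(nf)

        def link(j0, i0, j1, i1):
            a, b = idx[j0, i0], idx[j1, i1]
            rows.append(a)
            cols.append(b)
            vals.append(-1.0)
            rows.append(b)
            cols.append(a)
            vals.append(-1.0)
            diag[a] += 1.0
            diag[b] += 1.0

        jj, ii = np.nonzero(fluid)
        for j, i in zip(jj, ii):
            if i + 1 < nx and fluid[j, i + 1]:
                link(j, i, j, i + 1)
            if j + 1 < ny and fluid[j + 1, i]:
                link(j, i, j + 1, i)
        if self.periodic_y:
            for i in range(nx):
                if fluid[ny - 1, i] and fluid[0, i]:
                    link(ny - 1, i, 0, i)
        rows.extend(range(nf))
        cols.extend(range(nf))
        vals.extend(diag)
        A = coo_matrix((vals, (rows, cols)), shape=(nf, nf)).tocsr()
        A = A / self.h**2
        # pin one cell to fix the pressure constant (pure-Neumann otherwise)
        A = A.tolil()
        A[0, :] = 0.0
        A[0, 0] = 1.0
        self._lu = splu(csc_matrix(A))
        self._fluid_idx = idx
        self._nf = nf

    # ------------------------------------------------------------- boundaries

    def inlet_speed(self, t: float) -> float:
        if self.waveform is None:
            return 0.0
        return float(self.waveform.u(t))

    def apply_bcs(self, u: np.ndarray, v: np.ndarray, t: float) -> None:
        u[~self.u_interior] = 0.0
        v[~self.v_interior] = 0.0
        u_in = self.inlet_speed(t)
        q_in = 0.0
        if self.inlet_faces is not None:
            vm = self.inlet_faces["v_mask"]
            v[vm] = u_in  # plug inflow along +y
            um = self.inlet_faces["u_mask"]
            u[um] = 0.0
            q_in = u_in * self.h * int(vm.sum())
        for name, pf in self.outlets.items():
            frac = self.config.outlet_fractions.get(name, 0.0)
            if pf["F_unit"] == 0.0:
                continue
            s = frac * q_in / pf["F_unit"]
            ax, ay = pf["axis"]
            u[pf["u_mask"]] = s * ax
            v[pf["v_mask"]] = s * ay
        # tangential ghost reflection (no-slip at the wall face)
        u[self.u_ghost_dn] = -np.roll(u, -1, axis=0)[self.u_ghost_dn]
        u[self.u_ghost_up] = -np.roll(u, 1, axis=0)[self.u_ghost_up]
        v[self.v_ghost_lt] = -np.roll(v, -1, axis=1)[self.v_ghost_lt]
        v[self.v_ghost_rt] = -np.roll(v, 1, axis=1)[self.v_ghost_rt]
        if self.periodic_y:
            v[-1, :] = v[0, :]

    # ------------------------------------------------------------------ step

    def _eddy_viscosity(self, u: np.ndarray, v: np.ndarray) -> np.ndarray | float:
        if self.config.eddy_viscosity_model == "none":
            return 0.0
        h = self.h
        uc = 0.5 * (u[:, :-1] + u[:, 1:])
        vc = 0.5 * (v[:-1, :] + v[1:, :])
        dudx = (u[:, 1:] - u[:, :-1]) / h
        dvdy = (v[1:, :] - v[:-1, :]) / h
        dudy = np.gradient(uc, h, axis=0)
        dvdx = np.gradient(vc, h, axis=1)
        s12 = 0.5 * (dudy + dvdx)
        smag = np.sqrt(2 * dudx**2 + 2 * dvdy**2 + 4 * s12**2)
        nut = (self.config.smagorinsky_coeff * h) ** 2 * smag
        nut[~self.mask.fluid] = 0.0
        return nut

    def step(self, dt: float, momentum_source=None) -> None:
        """Advance the field by one time step of size ``dt``."""
        h = self.h
        nu = self.blood.nu
        u, v = self.u, self.v
        self.apply_bcs(u, v, self.t)

        umax = max(np.abs(u).max(), np.abs(v).max(), 1e-30)
        if umax * dt / h > 1.0:
            raise SolverError(
                f"CFL violation at t={self.t:.4f}: u_max*dt/h = {umax * dt / h:.2f}"
            )

        nut = self._eddy_viscosity(u, v)
        if isinstance(nut, np.ndarray):
            nut_u = np.zeros_like(u)
            nut_u[:, 1:-1] = 0.5 * (nut[:, :-1] + nut[:, 1:])
            nut_v = np.zeros_like(v)
            nut_v[1:-1, :] = 0.5 * (nut[:-1, :] + nut[1:, :])
        else:
            nut_u = nut_v = 0.0

        # --- u momentum ------------------------------------------------
        dudx_m = (u - np.roll(u, 1, axis=1)) / h
        dudx_p = (np.roll(u, -1, axis=1) - u) / h
        dudy_m = (u - np.roll(u, 1, axis=0)) / h
        dudy_p = (np.roll(u, -1, axis=0) - u) / h
        vpad = np.pad(v, ((0, 0), (1, 1)))
        V = 0.25 * (vpad[:-1, :-1] + vpad[:-1, 1:] + vpad[1:, :-1] + vpad[1:, 1:])
        adv_u = np.where(u > 0, u * dudx_m, u * dudx_p) + np.where(
            V > 0, V * dudy_m, V * dudy_p
        )
        lap_u = (
            np.roll(u, 1, axis=1)
            + np.roll(u, -1, axis=1)
            + np.roll(u, 1, axis=0)
            + np.roll(u, -1, axis=0)
            - 4 * u
        ) / h**2
        ustar = u + dt * (-adv_u + (nu + nut_u) * lap_u)

        # --- v momentum ------------------------------------------------
        dvdx_m = (v - np.roll(v, 1, axis=1)) / h
        dvdx_p = (np.roll(v, -1, axis=1) - v) / h
        dvdy_m = (v - np.roll(v, 1, axis=0)) / h
        dvdy_p = (np.roll(v, -1, axis=0) - v) / h
        upad = np.pad(u, ((1, 1), (0, 0)))
        U = 0.25 * (upad[:-1, :-1] + upad[:-1, 1:] + upad[1:, :-1] + upad[1:, 1:])
        adv_v = np.where(U > 0, U * dvdx_m, U * dvdx_p) + np.where(
            v > 0, v * dvdy_m, v * dvdy_p
        )
        lap_v = (
            np.roll(v, 1, axis=1)
            + np.roll(v, -1, axis=1)
            + np.roll(v, 1, axis=0)
            + np.roll(v, -1, axis=0)
            - 4 * v
        ) / h**2
        vstar = v + dt * (-adv_v + (nu + nut_v) * lap_v)

        if self.body_force is not None:
            fx, fy = self.body_force(self.t)
            ustar += dt * fx
            vstar += dt * fy
        if momentum_source is not None:
            su, sv = momentum_source
            ustar += dt * su
            vstar += dt * sv

        t_new = self.t + dt
        self.apply_bcs(ustar, vstar, t_new)

        # --- projection -------------------------------------------------
        fluid = self.mask.fluid
        if self.periodic_y:
            vstar[-1, :] = vstar[0, :]
        div = (ustar[:, 1:] - ustar[:, :-1] + vstar[1:, :] - vstar[:-1, :]) / h
        rhs = np.zeros(self._nf)
        # the assembled matrix is -laplacian (positive definite), hence -div
        rhs[self._fluid_idx[fluid]] = -div[fluid] / dt
        rhs[0] = 0.0
        phi = self._lu.solve(rhs)
        phi2d = np.zeros_like(self.p)
        phi2d[fluid] = phi

        gx = (phi2d[:, 1:] - phi2d[:, :-1]) / h
        ui = self.u_interior[:, 1:-1]
        ustar[:, 1:-1][ui] -= dt * gx[ui]
        gy = (phi2d[1:, :] - phi2d[:-1, :]) / h
        vi = self.v_interior[1:-1, :]
        vstar[1:-1, :][vi] -= dt * gy[vi]
        if self.periodic_y:
            gy0 = (phi2d[0, :] - phi2d[-1, :]) / h
            vi0 = self.v_interior[0, :]
            vstar[0, :][vi0] -= dt * gy0[vi0]
            vstar[-1, :] = vstar[0, :]

        div = (ustar[:, 1:] - ustar[:, :-1] + vstar[1:, :] - vstar[:-1, :]) / h
        self.last_div = float(np.abs(div[fluid]).max()) if fluid.any() else 0.0
        # dimensionless residual: max |div| scaled by the velocity scale over h
        uscale = max(float(np.abs(ustar).max()), float(np.abs(vstar).max()), 1e-12)
        if self.last_div * h / uscale > self.config.div_tol:
            raise SolverError(
                f"projection failed: normalized divergence "
                f"{self.last_div * h / umax:.3e} > {self.config.div_tol:g}"
            )

        self.u, self.v = ustar, vstar
        self.p = phi2d * self.blood.density  # dynamic pressure estimate
        self.t = t_new
        self.last_mass_err = self.mass_balance_error()

    def mass_balance_error(self) -> float:
        """Relative mismatch between inlet flux and summed outlet fluxes."""
        if self.inlet_faces is None:
            return 0.0
        q_in = self.inlet_speed(self.t) * self.h * int(self.inlet_faces["v_mask"].sum())
        if abs(q_in) < 1e-14:
            return 0.0
        q_out = 0.0
        for pf in self.outlets.values():
            q_out += float((self.u * pf["u_n"] * pf["u_mask"]).sum()) * self.h
            q_out += float((self.v * pf["v_n"] * pf["v_mask"]).sum()) * self.h
        return abs(q_out - q_in) / abs(q_in)

    def field(self) -> FlowField:
        return FlowField(self.t, self.u.copy(), self.v.copy(), self.p.copy(), self.mask)


def step_flow(
    field: FlowField,
    dt: float,
    waveform: FlowWaveform | None,
    mask: DomainMask,
    config: SolverConfig,
    body_force=None,
) -> FlowField:
    """Advance a :class:`FlowField` by ``dt`` (convenience wrapper).

    Builds a fresh solver per call; drivers that take many steps should use
    :class:`ProjectionSolver` directly to reuse the factorized projection.
    """
    solver = ProjectionSolver(mask, BloodProperties(), config, waveform, body_force)
    solver.u = field.u.copy()
    solver.v = field.v.copy()
    solver.p = field.p.copy()
    solver.t = field.t
    solver.step(dt)
    return solver.field()


@dataclass
class CycleHistory:
    """Snapshots of one periodic cardiac cycle at a fixed phase stride.

    ``uc``/``vc`` are stacks of cell-centered velocities with shape
    (n_snap, ny, nx); snapshot ``k`` holds the field at cycle phase
    ``k * T / n_snap``.  ``periodicity`` lists the cycle-to-cycle L2 change
    of the velocity field (a transient-decay diagnostic).
    """

    T: float
    uc: np.ndarray
    vc: np.ndarray
    mask: DomainMask
    periodicity: list[float]
    max_mass_err: float
    dt: float

    @property
    def n_snap(self) -> int:
        return self.uc.shape[0]

    def sample_velocity(self, points, t: float) -> np.ndarray:
        """Bilinear-in-space, linear-in-time periodic velocity sample (N, 2)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        h = self.mask.spacing
        gx = (p[:, 0] - self.mask.origin[0]) / h - 0.5
        gy = (p[:, 1] - self.mask.origin[1]) / h - 0.5
        f = (t % self.T) / self.T * self.n_snap
        k0 = int(f) % self.n_snap
        k1 = (k0 + 1) % self.n_snap
        w = f - int(f)
        u = (1 - w) * _bilinear(self.uc[k0], gx, gy) + w * _bilinear(self.uc[k1], gx, gy)
        v = (1 - w) * _bilinear(self.vc[k0], gx, gy) + w * _bilinear(self.vc[k1], gx, gy)
        return np.stack([u, v], axis=1)

    def snapshot_field(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        return self.uc[k], self.vc[k]


def run_cycles(
    condition: HemodynamicCondition,
    mask: DomainMask,
    config: SolverConfig,
    n_cycles: int | None = None,
) -> CycleHistory:
    """Run the pulsatile problem for ``n_cycles`` and record the last cycle.

    The time step is set from the advective CFL number at peak inlet
    velocity and rounded so a cycle holds an integer number of steps that is
    a multiple of the snapshot count.  Returns the recorded periodic cycle.
    """
    n_cycles = int(config.n_cycles if n_cycles is None else n_cycles)
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2 (one transient + one recorded)")
    wf = condition.waveform
    h = mask.spacing
    if config.dt is not None:
        dt_target = config.dt
    else:
        dt_target = config.cfl * h / wf.U_peak
    n_snap = int(config.snapshots_per_cycle)
    steps_per_snap = max(1, math.ceil(wf.T / dt_target / n_snap))
    steps_per_cycle = steps_per_snap * n_snap
    dt = wf.T / steps_per_cycle

    solver = ProjectionSolver(mask, condition.blood, config, wf)
    ny, nx = mask.shape
    uc = np.zeros((n_snap, ny, nx))
    vc = np.zeros((n_snap, ny, nx))
    periodicity: list[float] = []
    prev_u = prev_v = None
    max_mass_err = 0.0
    for cycle in range(n_cycles):
        last = cycle == n_cycles - 1
        for s in range(steps_per_cycle):
            if last and s % steps_per_snap == 0:
                k = s // steps_per_snap
                f = solver.field()
                uc[k] = f.uc
                vc[k] = f.vc
            solver.step(dt)
            max_mass_err = max(max_mass_err, solver.last_mass_err)
        if prev_u is not None:
            diff = math.sqrt(
                float(((solver.u - prev_u) ** 2).sum() + ((solver.v - prev_v) ** 2).sum())
            )
            periodicity.append(diff)
        prev_u = solver.u.copy()
        prev_v = solver.v.copy()
    return CycleHistory(
        T=wf.T,
        uc=uc,
        vc=vc,
        mask=mask,
        periodicity=periodicity,
        max_mass_err=max_mass_err,
        dt=dt,
    )


# ---------------------------------------------------------------- wall shear


def wall_segments(mask: DomainMask):
    """Wall-adjacent fluid-cell segments with outward wall normals.

    Returns arrays ``(x, y, nx_dir, ny_dir, s)`` where (x, y) is the fluid
    cell center, (nx_dir, ny_dir) the unit direction from the cell toward
    its wall neighbor, and ``s`` an approximate arc-length coordinate from
    greedy nearest-neighbor chaining of the segments.
    """
    labels = mask.labels
    fluid = labels == FLUID
    xc, yc = mask.cell_centers()
    segs = []
    for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        shifted = np.roll(labels, (-dj, -di), axis=(0, 1)) == WALL
        # roll wraps at the domain edge; padded wall rings make this safe
        hit = fluid & shifted
        jj, ii = np.nonzero(hit)
        for j, i in zip(jj, ii):
            segs.append((xc[i], yc[j], float(di), float(dj)))
    if not segs:
        return np.zeros((0, 5))
    arr = np.array(segs)
    # greedy chain for an arc-length coordinate
    n = len(arr)
    order = np.zeros(n, dtype=int)
    used = np.zeros(n, dtype=bool)
    cur = int(np.lexsort((arr[:, 0], arr[:, 1]))[0])
    s_coord = np.zeros(n)
    used[cur] = True
    order[0] = cur
    s = 0.0
    for k in range(1, n):
        d2 = np.sum((arr[:, :2] - arr[cur, :2]) ** 2, axis=1)
        d2[used] = np.inf
        nxt = int(np.argmin(d2))
        s += math.sqrt(float(d2[nxt]))
        s_coord[nxt] = s
        used[nxt] = True
        order[k] = nxt
        cur = nxt
    out = np.column_stack([arr, s_coord])
    return out


def compute_wss(field, mask: DomainMask, blood: BloodProperties, segments=None):
    """Wall shear stress magnitude per wall-adjacent segment (Pa).

    ``field`` is a :class:`FlowField` or a ``(uc, vc)`` tuple of
    cell-centered velocities.  The stress is the viscous tangential-velocity
    gradient evaluated one half-cell from the wall:
    ``tau_w = mu * |u_t(h/2)| / (h/2)``.

    Returns a record array with fields x, y, s (arc length), tau.
    """
    if isinstance(field, FlowField):
        uc, vc = field.uc, field.vc
    else:
        uc, vc = field
    if segments is None:
        segments = wall_segments(mask)
    h = mask.spacing
    mu = blood.viscosity
    x0, y0 = mask.origin
    i = ((segments[:, 0] - x0) / h - 0.5).round().astype(int)
    j = ((segments[:, 1] - y0) / h - 0.5).round().astype(int)
    nxd, nyd = segments[:, 2], segments[:, 3]
    uu = uc[j, i]
    vv = vc[j, i]
    # tangential = velocity minus its wall-normal component
    un = uu * nxd + vv * nyd
    ut = np.hypot(uu - un * nxd, vv - un * nyd)
    tau = mu * ut / (h / 2)
    out = np.zeros(len(tau), dtype=[("x", float), ("y", float), ("s", float), ("tau", float)])
    out["x"] = segments[:, 0]
    out["y"] = segments[:, 1]
    out["s"] = segments[:, 4]
    out["tau"] = tau
    return out


def cycle_peak_mean_wss(history: CycleHistory, blood: BloodProperties) -> float:
    """Cycle maximum of the spatial-mean wall shear stress (Pa)."""
    segs = wall_segments(history.mask)
    best = 0.0
    for k in range(history.n_snap):
        wss = compute_wss(history.snapshot_field(k), history.mask, blood, segments=segs)
        best = max(best, float(wss["tau"].mean()))
    return best
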