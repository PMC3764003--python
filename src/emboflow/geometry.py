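"""Idealized 2-D aortic-arch geometry and its rasterization.

The computational domain is a planar reduction of an idealized aortic arch:
a straight ascending leg (inlet at the bottom), a 180-degree curved channel
of width ``D_AA``, three straight branch stubs (BCA, LCCA, LSA) leaving the
outer wall of the bend, and a straight descending leg ending in the
descending outlet.  Two morphometric cases are provided, corresponding to
the upper and lower ranges of human aortic-branch diameters.

Coordinates: continuous 2-D Cartesian, origin at the inlet center, inlet
flow direction +y.  The bend center sits at ``(arch_radius, leg_length)``.
Masks are cell-centered with 0-based ``[row, col]`` = ``[y, x]`` indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "ArchGeometry",
    "DomainMask",
    "build_arch",
    "rasterize",
    "channel_mask",
    "WALL",
    "FLUID",
    "INLET",
    "OUTLET_BCA",
    "OUTLET_LCCA",
    "OUTLET_LSA",
    "OUTLET_DESC",
    "BRANCH_NAMES",
    "OUTLET_LABELS",
]

# cell labels
WALL = 0
FLUID = 1
INLET = 2
OUTLET_BCA = 3
OUTLET_LCCA = 4
OUTLET_LSA = 5
OUTLET_DESC = 6

BRANCH_NAMES = ("BCA", "LCCA", "LSA")
OUTLET_LABELS = {
    "BCA": OUTLET_BCA,
    "LCCA": OUTLET_LCCA,
    "LSA": OUTLET_LSA,
    "desc": OUTLET_DESC,
}

#: branch and trunk diameters (m) for the two morphometric cases
CASE_DIAMETERS = {
    "I": {"D_AA": 29.0e-3, "D_BCA": 19.0e-3, "D_LCCA": 14.3e-3, "D_LSA": 16.7e-3},
    "II": {"D_AA": 27.5e-3, "D_BCA": 11.4e-3, "D_LCCA": 7.5e-3, "D_LSA": 10.1e-3},
}


class GeometryError(ValueError):
    """Raised for invalid geometric parameters or rasterization requests."""


@dataclass(frozen=True)
class ArchGeometry:
    """Parametric planar aortic arch (all lengths in meters)."""

    case_label: str
    D_AA: float
    D_BCA: float
    D_LCCA: float
    D_LSA: float
    D_desc: float
    arch_radius: float
    branch_arc: tuple[float, float, float]  # radians along the bend, ascending side first
    branch_length: tuple[float, float, float]
    leg_length: float

    def __post_init__(self) -> None:
        dia = [self.D_AA, self.D_BCA, self.D_LCCA, self.D_LSA, self.D_desc]
        if any(d <= 0 for d in dia):
            raise GeometryError("all diameters must be positive")
        for name, d in zip(BRANCH_NAMES, self.branch_diameters):
            if d >= self.D_AA:
                raise GeometryError(f"branch diameter {name} must be < D_AA")
        arcs = self.branch_arc
        if not (0.0 < arcs[0] < arcs[1] < arcs[2] < math.pi):
            raise GeometryError("branch arcs must be strictly increasing within the bend")
        if self.arch_radius <= self.D_AA / 2:
            raise GeometryError("arch_radius must exceed D_AA/2")
        if any(l <= 0 for l in self.branch_length) or self.leg_length <= 0:
            raise GeometryError("lengths must be positive")
        # adjacent branch edges must not overlap on the outer wall
        r_out = self.outer_radius
        for k in range(2):
            gap = (arcs[k + 1] - arcs[k]) * r_out
            half = (self.branch_diameters[k] + self.branch_diameters[k + 1]) / 2
            if gap < half:
                raise GeometryError(
                    f"branches {BRANCH_NAMES[k]} and {BRANCH_NAMES[k + 1]} overlap"
                )

    # ---- derived quantities -------------------------------------------------

    @property
    def branch_diameters(self) -> tuple[float, float, float]:
        return (self.D_BCA, self.D_LCCA, self.D_LSA)

    @property
    def bend_center(self) -> tuple[float, float]:
        return (self.arch_radius, self.leg_length)

    @property
    def outer_radius(self) -> float:
        return self.arch_radius + self.D_AA / 2

    @property
    def desc_center_x(self) -> float:
        return 2 * self.arch_radius

    def branch_axis(self, k: int) -> tuple[float, float]:
        """Unit outward direction of branch ``k`` (radial from the bend center)."""
        theta = math.pi - self.branch_arc[k]
        return (math.cos(theta), math.sin(theta))

    def branch_port_radius(self, k: int) -> float:
        """Radial distance from the bend center to the branch outlet plane."""
        return self.outer_radius + self.branch_length[k]

    def analytic_area(self) -> float:
        """Planform fluid area of the parametric shape (m^2)."""
        legs = self.D_AA * self.leg_length + self.D_desc * self.leg_length
        bend = math.pi * self.arch_radius * self.D_AA
        stubs = sum(d * l for d, l in zip(self.branch_diameters, self.branch_length))
        return legs + bend + stubs

    # ---- point membership and signed distance -------------------------------

    def _branch_local(self, k: int, x, y):
        """Along-axis and lateral coordinates relative to the bend center."""
        ex, ey = self.branch_axis(k)
        px, py = x - self.bend_center[0], y - self.bend_center[1]
        s = px * ex + py * ey
        lat = -px * ey + py * ex
        return s, lat

    def contains(self, x, y):
        """Boolean membership of points in the fluid region (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        D, R, L = self.D_AA, self.arch_radius, self.leg_length
        inside = (np.abs(x) <= D / 2) & (y >= 0) & (y <= L)
        inside |= (np.abs(x - self.desc_center_x) <= self.D_desc / 2) & (y >= 0) & (y <= L)
        r = np.hypot(x - R, y - L)
        inside |= (y >= L) & (r >= R - D / 2) & (r <= R + D / 2)
        for k, Db in enumerate(self.branch_diameters):
            s, lat = self._branch_local(k, x, y)
            inside |= (
                (s >= R)
                & (s <= self.branch_port_radius(k))
                & (np.abs(lat) <= Db / 2)
            )
        return inside

    def sdf(self, points, port_extension: float = 0.0):
        """Signed distance to the fluid region (negative inside).

        ``port_extension`` lengthens every port channel beyond its port plane
        so that particle wall-handling does not block port crossings; exits
        are detected by the port-plane predicates, not by the distance field.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = p[:, 0], p[:, 1]
        D, R, L = self.D_AA, self.arch_radius, self.leg_length
        E = float(port_extension)
        # overlap the legs slightly into the bend so the union has no seams
        dl = _sdf_box(x, y, 0.0, (L - E) / 2 + D / 8, D / 2, (L + E) / 2 + D / 8)
        dd = _sdf_box(
            x, y, self.desc_center_x, (L - E) / 2 + D / 8, self.D_desc / 2, (L + E) / 2 + D / 8
        )
        r = np.hypot(x - R, y - L)
        ring = np.abs(r - R) - D / 2
        half_ring = np.maximum(ring, L - y)
        d = np.minimum(np.minimum(dl, dd), half_ring)
        for k, Db in enumerate(self.branch_diameters):
            s, lat = self._branch_local(k, x, y)
            s0, s1 = R - D / 4, self.branch_port_radius(k) + E
            db = _sdf_box(s, lat, (s0 + s1) / 2, 0.0, (s1 - s0) / 2, Db / 2)
            d = np.minimum(d, db)
        return d

    def wall_normal(self, points, port_extension: float = 0.0, eps: float = 1e-6):
        """Outward unit normal of the distance field at ``points`` (N, 2)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        gx = (
            self.sdf(p + [eps, 0.0], port_extension)
            - self.sdf(p - [eps, 0.0], port_extension)
        ) / (2 * eps)
        gy = (
            self.sdf(p + [0.0, eps], port_extension)
            - self.sdf(p - [0.0, eps], port_extension)
        ) / (2 * eps)
        g = np.stack([gx, gy], axis=1)
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return g / norm

    # ---- port predicates (used by trajectory classification) ----------------

    def port_status(self, points, tol: float = 0.0):
        """Classify points beyond a port plane.

        Returns an integer array: 0 for in-domain, otherwise the port cell
        label (``OUTLET_*`` or ``INLET`` for backflow out of the inlet).
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = p[:, 0], p[:, 1]
        out = np.zeros(len(p), dtype=int)
        D = self.D_AA
        below = y < -tol
        out[below & (np.abs(x) <= D / 2 + tol)] = INLET
        out[below & (np.abs(x - self.desc_center_x) <= self.D_desc / 2 + tol)] = OUTLET_DESC
        for k, (name, Db) in enumerate(zip(BRANCH_NAMES, self.branch_diameters)):
            s, lat = self._branch_local(k, x, y)
            hit = (s > self.branch_port_radius(k) + tol) & (np.abs(lat) <= Db / 2 + tol)
            out[hit] = OUTLET_LABELS[name]
        return out

    def branch_region(self, points):
        """Index (0=BCA, 1=LCCA, 2=LSA) of the branch stub containing each
        point beyond the branch mouth on the outer wall, else -1."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(p), -1, dtype=int)
        for k, Db in enumerate(self.branch_diameters):
            s, lat = self._branch_local(k, p[:, 0], p[:, 1])
            hit = (s > self.outer_radius) & (np.abs(lat) <= Db / 2)
            out[hit] = k
        return out

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "case_label": self.case_label,
            "D_AA": self.D_AA,
            "D_BCA": self.D_BCA,
            "D_LCCA": self.D_LCCA,
            "D_LSA": self.D_LSA,
            "D_desc": self.D_desc,
            "arch_radius": self.arch_radius,
            "branch_arc": list(self.branch_arc),
            "branch_length": list(self.branch_length),
            "leg_length": self.leg_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchGeometry":
        d = dict(d)
        d["branch_arc"] = tuple(d["branch_arc"])
        d["branch_length"] = tuple(d["branch_length"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ArchGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sdf_box(x, y, cx, cy, hx, hy):
    """Signed distance to an axis-aligned box given center and half-sizes."""
    qx = np.abs(x - cx) - hx
    qy = np.abs(y - cy) - hy
    outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
    inside = np.minimum(np.maximum(qx, qy), 0.0)
    return outside + inside


def build_arch(case_label: str, overrides: dict | None = None) -> ArchGeometry:
    """Build the idealized arch for morphometric case ``I`` or ``II``.

    ``overrides`` may replace any declared :class:`ArchGeometry` field;
    defaults follow the parametric conventions: centerline bend radius
    ``2 * D_AA``, branch stubs of ``3 x`` their diameter directed radially
    outward, branch take-offs at 60/90/120 degrees along the bend.
    """
    if case_label not in CASE_DIAMETERS:
        raise GeometryError(f"unknown case label {case_label!r}; expected 'I' or 'II'")
    dia = CASE_DIAMETERS[case_label]
    params = {
        "case_label": case_label,
        **dia,
        "D_desc": dia["D_AA"],
        "arch_radius": 2 * dia["D_AA"],
        "branch_arc": (math.pi / 3, math.pi / 2, 2 * math.pi / 3),
        "branch_length": tuple(3 * dia[f"D_{n}"] for n in BRANCH_NAMES),
        "leg_length": dia["D_AA"],
    }
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise GeometryError(f"unknown override fields: {sorted(unknown)}")
        params.update(overrides)
        for key in ("branch_arc", "branch_length"):
            params[key] = tuple(params[key])
    return ArchGeometry(**params)


@dataclass
class DomainMask:
    """Cell-labeled rasterization of a flow domain.

    ``labels`` is a (ny, nx) int8 array of cell labels; ``origin`` is the
    lower-left corner of cell (0, 0); cell centers sit at
    ``origin + (index + 0.5) * spacing``.  ``port_axes`` maps each port label
    to its outward unit axis.
    """

    spacing: float
    origin: tuple[float, float]
    labels: np.ndarray
    port_axes: dict[int, tuple[float, float]]
    geometry: ArchGeometry | None = None
    periodic_y: bool = False
    _edt: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def fluid(self) -> np.ndarray:
        return self.labels == FLUID

    def cell_centers(self):
        ny, nx = self.labels.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return x, y

    def port_cells(self, label: int) -> np.ndarray:
        return np.argwhere(self.labels == label)

    def port_span(self, label: int) -> float:
        """Extent of a port's cells along the port-cap direction (m)."""
        cells = self.port_cells(label)
        if len(cells) == 0:
            raise GeometryError(f"no cells with label {label}")
        ax, ay = self.port_axes[label]
        x, y = self.cell_centers()
        px = x[cells[:, 1]]
        py = y[cells[:, 0]]
        lat = -px * ay + py * ax  # coordinate perpendicular to the outward axis
        return float(lat.max() - lat.min()) + self.spacing

    def validate(self) -> None:
        """Check the mask invariants (port disjointness, adjacency, spans)."""
        fluid = self.fluid
        for label in self.port_axes:
            cells = self.labels == label
            if not cells.any():
                raise GeometryError(f"port {label} has no cells")
            adj = _adjacent_to(cells)
            if not (adj & fluid).any():
                raise GeometryError(f"port {label} not adjacent to fluid")
        n_comp = ndimage.label(fluid)[1]
        if n_comp != 1:
            raise GeometryError(f"fluid region has {n_comp} components")

    def signed_distance(self, points):
        """Signed distance to fluid, interpolated from a distance transform.

        A coarse fallback for masks without an analytic parent geometry
        (straight channels); arch runs use :meth:`ArchGeometry.sdf`.
        """
        if self._edt is None:
            fluid = self.fluid
            inside = ndimage.distance_transform_edt(fluid, sampling=self.spacing)
            outside = ndimage.distance_transform_edt(~fluid, sampling=self.spacing)
            object.__setattr__(self, "_edt", outside - inside)
        p = np.atleast_2d(np.asarray(points, dtype=float))
        gx = (p[:, 0] - self.origin[0]) / self.spacing - 0.5
        gy = (p[:, 1] - self.origin[1]) / self.spacing - 0.5
        from .flow_solver import _bilinear  # local import to avoid cycle

        return _bilinear(self._edt, gx, gy)


def _adjacent_to(cells: np.ndarray) -> np.ndarray:
    adj = np.zeros_like(cells)
    adj[:-1] |= cells[1:]
    adj[1:] |= cells[:-1]
    adj[:, :-1] |= cells[:, 1:]
    adj[:, 1:] |= cells[:, :-1]
    return adj


def rasterize(geometry: ArchGeometry, grid_spacing: float) -> DomainMask:
    """Rasterize the arch into a labeled cell mask.

    The grid must resolve the narrowest branch with at least six cells.
    Port cells are the non-fluid cells adjacent to fluid lying beyond each
    port plane; the inlet spans ``D_AA`` at ``y = 0``.
    """
    h = float(grid_spacing)
    min_branch = min(geometry.branch_diameters)
    if h > min_branch / 6:
        raise GeometryError(
            f"grid spacing {h:g} m too coarse: narrowest branch "
            f"({min_branch:g} m) needs spacing <= {min_branch / 6:g} m"
        )
    # bounding box with margin for wall padding plus one port-cell ring
    margin = 3 * h
    cands_x = [-geometry.D_AA / 2, geometry.desc_center_x + geometry.D_desc / 2]
    cands_y = [0.0, geometry.leg_length + geometry.arch_radius + geometry.D_AA / 2]
    for k, Db in enumerate(geometry.branch_diameters):
        ex, ey = geometry.branch_axis(k)
        rp = geometry.branch_port_radius(k)
        cx, cy = geometry.bend_center
        tip = np.array([cx + rp * ex, cy + rp * ey])
        for sgn in (-1, 1):
            corner = tip + sgn * (Db / 2) * np.array([-ey, ex])
            cands_x.append(corner[0])
            cands_y.append(corner[1])
    x_lo, x_hi = min(cands_x) - margin, max(cands_x) + margin
    y_lo, y_hi = -margin, max(cands_y) + margin
    nx = int(math.ceil((x_hi - x_lo) / h))
    ny = int(math.ceil((y_hi - y_lo) / h))
    xc = x_lo + (np.arange(nx) + 0.5) * h
    yc = y_lo + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc)

    labels = np.zeros((ny, nx), dtype=np.int8)
    fluid = geometry.contains(X, Y)
    labels[fluid] = FLUID
    n_comp = ndimage.label(fluid)[1]
    if n_comp != 1:
        raise GeometryError(
            f"rasterized fluid region has {n_comp} connected components"
        )

    adj = _adjacent_to(fluid)
    cand = adj & ~fluid
    D = geometry.D_AA
    # inlet and descending outlet: candidate cells below y = 0
    inlet = cand & (Y < 0) & (np.abs(X) <= D / 2)
    desc = cand & (Y < 0) & (np.abs(X - geometry.desc_center_x) <= geometry.D_desc / 2)
    labels[inlet] = INLET
    labels[desc] = OUTLET_DESC
    port_axes: dict[int, tuple[float, float]] = {
        INLET: (0.0, -1.0),
        OUTLET_DESC: (0.0, -1.0),
    }
    for k, (name, Db) in enumerate(zip(BRANCH_NAMES, geometry.branch_diameters)):
        s, lat = geometry._branch_local(k, X, Y)
        hit = cand & (s >= geometry.branch_port_radius(k) - h) & (np.abs(lat) <= Db / 2)
        label = OUTLET_LABELS[name]
        if (labels[hit] != WALL).any():
            raise GeometryError(f"port {name} overlaps another port")
        labels[hit] = label
        port_axes[label] = geometry.branch_axis(k)

    mask = DomainMask(
        spacing=h,
        origin=(x_lo, y_lo),
        labels=labels,
        port_axes=port_axes,
        geometry=geometry,
    )
    mask.validate()
    return mask


def channel_mask(
    width: float,
    length: float,
    grid_spacing: float,
    periodic: bool = False,
) -> DomainMask:
    """Straight vertical channel mask for solver validation.

    Flow direction +y.  Non-periodic channels carry an inlet row at the
    bottom and a descending-outlet row at the top; periodic channels have
    fluid wrapping in y (used for body-force-driven oscillatory flow).
    """
    h = float(grid_spacing)
    nxf = int(round(width / h))
    nyf = int(round(length / h))
    if nxf < 4 or nyf < 1:
        raise GeometryError("channel too small for the requested spacing")
    pad = 2
    nx = nxf + 2 * pad
    if periodic:
        ny = nyf
        labels = np.zeros((ny, nx), dtype=np.int8)
        labels[:, pad : pad + nxf] = FLUID
        origin = (-width / 2 - pad * h, 0.0)
        mask = DomainMask(
            spacing=h,
            origin=origin,
            labels=labels,
            port_axes={},
            periodic_y=True,
        )
        return mask
    ny = nyf + 2 * pad
    labels = np.zeros((ny, nx), dtype=np.int8)
    labels[pad : pad + nyf, pad : pad + nxf] = FLUID
    labels[pad - 1, pad : pad + nxf] = INLET
    labels[pad + nyf, pad : pad + nxf] = OUTLET_DESC
    origin = (-width / 2 - pad * h, -pad * h)
    mask = DomainMask(
        spacing=h,
        origin=origin,
        labels=labels,
        port_axes={INLET: (0.0, -1.0), OUTLET_DESC: (0.0, 1.0)},
    )
    mask.validate()
    return mask
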