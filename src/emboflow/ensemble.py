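"""Release grids, experiment driver, and stroke-propensity statistics.

The study statistic is *stroke propensity*: the percent ratio of released
clots whose trajectories end in the (left common) carotid artery to all
clots released.  The release ensemble is a full factorial grid of 17 inlet
positions (spanning 0-40% of the inlet radius about the centerline), an
ejection-speed list, a diameter list (2-6 mm), and the three ejection
moments of the cardiac cycle (begin-systole, accelerating, peak).  With the
study defaults the grid holds 17 x 10 x 5 x 3 = 2550 release specs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clot_transport import ForceModel, simulate_clots
from .flow_solver import (
    CycleHistory,
    SolverConfig,
    cycle_peak_mean_wss,
    run_cycles,
)
from .geometry import ArchGeometry, rasterize
from .hemodynamics import HemodynamicCondition, ejection_times

__all__ = [
    "ReleaseGrid",
    "PropensityResult",
    "TransportConfig",
    "make_release_grid",
    "stroke_propensity",
    "run_experiment",
    "propensity_table",
    "overall_propensity",
    "compare_conditions",
    "EJECTION_LABELS",
]

EJECTION_LABELS = ("begin", "accel", "peak")
STATUS_TO_OUTCOME = {
    "exited_BCA": "BCA",
    "exited_LCCA": "LCCA",
    "exited_LSA": "LSA",
    "exited_desc": "desc",
}
OUTCOMES = ("BCA", "LCCA", "LSA", "desc", "retained")
CAROTID_OUTCOME = "LCCA"  # headline statistic counts left-carotid capture only


@dataclass(frozen=True)
class ReleaseGrid:
    """Full factorial ensemble of release specifications.

    ``positions`` are lateral offsets (m) from the inlet centerline;
    ``speeds`` in m/s; ``diameters`` in m; ``ejection_labels`` name the
    cardiac-cycle moments resolved per condition by
    :func:`~emboflow.hemodynamics.ejection_times`.
    """

    positions: tuple[float, ...]
    speeds: tuple[float, ...]
    diameters: tuple[float, ...]
    ejection_labels: tuple[str, ...]
    inlet_radius: float

    def __post_init__(self) -> None:
        r_max = 0.4 * self.inlet_radius
        if any(abs(p) > r_max * (1 + 1e-9) for p in self.positions):
            raise ValueError("release positions must lie within 40% of the inlet radius")
        if any(s < 0 for s in self.speeds):
            raise ValueError("ejection speeds must be non-negative")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("clot diameters must be positive")
        unknown = set(self.ejection_labels) - set(EJECTION_LABELS)
        if unknown:
            raise ValueError(f"unknown ejection labels: {sorted(unknown)}")

    @property
    def size(self) -> int:
        return (
            len(self.positions)
            * len(self.speeds)
            * len(self.diameters)
            * len(self.ejection_labels)
        )

    def specs(self):
        """Iterate (position_index, position, speed, diameter, ejection_label)."""
        for (ip, p), s, d, e in itertools.product(
            enumerate(self.positions, start=1), self.speeds, self.diameters,
            self.ejection_labels,
        ):
            yield ip, p, s, d, e


def make_release_grid(
    D_inlet: float,
    n_positions: int = 17,
    speeds=None,
    diameters=None,
    ejection_labels=EJECTION_LABELS,
    preset: str | None = None,
) -> ReleaseGrid:
    """Build a release grid for an inlet of diameter ``D_inlet``.

    Defaults reproduce the study grid: 17 equispaced positions on the inlet
    chord spanning +/-40% of the radius, 10 speeds uniformly spanning
    0-0.8 m/s, diameters 2-6 mm, and all three ejection moments (2550
    specs).  ``preset='speed_sweep'`` selects the 0.1-0.7 m/s (step 0.1)
    ejection-speed sweep instead.
    """
    radius = D_inlet / 2
    positions = tuple(np.linspace(-0.4 * radius, 0.4 * radius, n_positions))
    if preset == "speed_sweep":
        speeds = tuple(np.round(np.arange(0.1, 0.7001, 0.1), 10))
    elif speeds is None:
        speeds = tuple(np.linspace(0.0, 0.8, 10))
    else:
        speeds = tuple(speeds)
    diameters = tuple(diameters) if diameters is not None else tuple(
        d * 1e-3 for d in (2, 3, 4, 5, 6)
    )
    return ReleaseGrid(
        positions=positions,
        speeds=speeds,
        diameters=diameters,
        ejection_labels=tuple(ejection_labels),
        inlet_radius=radius,
    )


def stroke_propensity(carotid_count: int, n_released: int) -> float:
    """Percent of released clots captured by the carotid, to 1 d.p."""
    if n_released <= 0:
        raise ValueError("n_released must be positive")
    if not (0 <= carotid_count <= n_released):
        raise ValueError("carotid count must be between 0 and n_released")
    return round(100.0 * carotid_count / n_released, 1)


@dataclass(frozen=True)
class PropensityResult:
    """Per-branch capture statistics for one stratum of the ensemble."""

    keys: dict
    counts: dict
    n_released: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_released:
            raise ValueError("outcome counts must sum to the ensemble size")

    @property
    def propensity(self) -> float:
        return stroke_propensity(self.counts.get(CAROTID_OUTCOME, 0), self.n_released)


@dataclass(frozen=True)
class TransportConfig:
    """Clot-transport parameters.

    ``dt`` is the particle time step (s); ``t_max_cycles`` the integration
    horizon after release in cardiac cycles (retained clots count as
    non-embolizing); ``release_offset_frac`` places the release plane this
    fraction of the inlet diameter above the inlet.
    """

    dt: float = 1.0e-3
    t_max_cycles: float = 5.0
    release_offset_frac: float = 0.1
    density: float = 1080.0
    force_model: ForceModel = field(default_factory=ForceModel)


def run_experiment(
    condition: HemodynamicCondition,
    geometry: ArchGeometry,
    grid: ReleaseGrid,
    solver_config: SolverConfig | None = None,
    transport_config: TransportConfig | None = None,
    history: CycleHistory | None = None,
) -> pd.DataFrame:
    """Run the full embolization experiment for one flow condition.

    Solves (or reuses) the periodic flow field, releases every spec of the
    grid, and returns a tidy table with one row per released clot:
    columns ``position_index, x0, speed, diameter_mm, ejection, status,
    exit_time``.  Deterministic given configs.
    """
    solver_config = solver_config or SolverConfig()
    transport_config = transport_config or TransportConfig()
    if history is None:
        spacing = solver_config.grid_spacing or geometry.D_AA / 32
        mask = rasterize(geometry, spacing)
        history = run_cycles(condition, mask, solver_config)

    t_begin, t_accel, t_peak = ejection_times(condition.waveform)
    eject_time = {"begin": t_begin, "accel": t_accel, "peak": t_peak}
    y0 = transport_config.release_offset_frac * geometry.D_AA
    t_horizon = transport_config.t_max_cycles * condition.waveform.T

    frames = []
    for label in grid.ejection_labels:
        t0 = eject_time[label]
        specs = [
            (ip, p, s, d)
            for (ip, p), s, d in itertools.product(
                enumerate(grid.positions, start=1), grid.speeds, grid.diameters
            )
        ]
        pos = np.array([[p, y0] for (_, p, _, _) in specs])
        vel = np.array([[0.0, s] for (_, _, s, _) in specs])
        dia = np.array([d for (_, _, _, d) in specs])
        statuses, exit_times, final_pos, _ = simulate_clots(
            history.sample_velocity,
            geometry,
            pos,
            vel,
            dia,
            t0=t0,
            t_max=t0 + t_horizon,
            dt=transport_config.dt,
            force_model=transport_config.force_model,
            blood=condition.blood,
            density=transport_config.density,
        )
        # outcome: exit through a port, or trajectory ending inside a branch
        # stub at the horizon (the statistic counts where trajectories end up)
        outcome = np.array([STATUS_TO_OUTCOME.get(st, "retained") for st in statuses],
                           dtype=object)
        stuck = outcome == "retained"
        if stuck.any():
            region = geometry.branch_region(final_pos[stuck])
            names = np.array(["BCA", "LCCA", "LSA"], dtype=object)
            inb = region >= 0
            out_stuck = outcome[stuck]
            out_stuck[inb] = names[region[inb]]
            outcome[stuck] = out_stuck
        frames.append(
            pd.DataFrame(
                {
                    "condition": condition.label,
                    "case": geometry.case_label,
                    "position_index": [ip for (ip, _, _, _) in specs],
                    "x0": pos[:, 0],
                    "speed": vel[:, 1],
                    "diameter_mm": dia * 1e3,
                    "ejection": label,
                    "status": statuses,
                    "outcome": outcome,
                    "exit_time": exit_times,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if len(df) != grid.size:
        raise RuntimeError("row count does not match the release-grid size")
    return df


def propensity_table(df: pd.DataFrame, by) -> pd.DataFrame:
    """Stratified per-branch counts and stroke propensity.

    ``by`` is a column list (e.g. ``["diameter_mm"]`` for the bar-chart
    strata).  Propensity is percent LCCA capture per stratum, to 1 d.p.
    """
    by = list(by)
    rows = []
    for keys, sub in df.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        counts = {oc: int((sub["outcome"] == oc).sum()) for oc in OUTCOMES}
        res = PropensityResult(
            keys=dict(zip(by, keys)), counts=counts, n_released=len(sub)
        )
        rows.append(
            {**res.keys, **counts, "n_released": res.n_released,
             "propensity": res.propensity}
        )
    return pd.DataFrame(rows)


def overall_propensity(df: pd.DataFrame) -> float:
    """Aggregate propensity: total carotid captures over total released."""
    return stroke_propensity(int((df["outcome"] == CAROTID_OUTCOME).sum()), len(df))


def compare_conditions(df_normal: pd.DataFrame, df_af: pd.DataFrame, by=("diameter_mm",)):
    """Per-stratum propensity deltas (AF minus normal) and overall values.

    Returns ``(table, summary)``: the merged per-stratum table with a
    ``delta`` column, and a dict with overall propensities per condition and
    the maximum per-stratum difference.
    """
    by = list(by)
    tn = propensity_table(df_normal, by)
    ta = propensity_table(df_af, by)
    merged = tn.merge(ta, on=by, suffixes=("_normal", "_af"), validate="one_to_one")
    if len(merged) != len(tn) or len(merged) != len(ta):
        raise ValueError("stratification keys do not match between conditions")
    merged["delta"] = merged["propensity_af"] - merged["propensity_normal"]
    summary = {
        "overall_normal": overall_propensity(df_normal),
        "overall_af": overall_propensity(df_af),
        "max_delta": float(merged["delta"].max()),
    }
    summary["overall_delta"] = round(summary["overall_af"] - summary["overall_normal"], 1)
    return merged, summary


def wss_comparison(
    history_normal: CycleHistory,
    history_af: CycleHistory,
    blood,
) -> dict:
    """Cycle-peak spatial-mean wall shear stress per condition (Pa)."""
    return {
        "normal": cycle_peak_mean_wss(history_normal, blood),
        "af": cycle_peak_mean_wss(history_af, blood),
    }
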