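"""Minimal legacy-ASCII VTK writers for inspection output.

Writes STRUCTURED_POINTS files for cell-labeled masks and cell-centered
fields, and POLYDATA polylines for clot trajectories.  The legacy ASCII
format is trivial to emit and opens directly in ParaView.
"""

from __future__ import annotations

import numpy as np

from .geometry import DomainMask

__all__ = ["write_mask_vtk", "write_field_vtk", "write_trajectories_vtk"]


def _header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def _structured_points(fh, mask: DomainMask) -> None:
    ny, nx = mask.shape
    h = mask.spacing
    fh.write("DATASET STRUCTURED_POINTS\n")
    fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
    fh.write(f"ORIGIN {mask.origin[0]:.9g} {mask.origin[1]:.9g} 0\n")
    fh.write(f"SPACING {h:.9g} {h:.9g} {h:.9g}\n")
    fh.write(f"CELL_DATA {nx * ny}\n")


def write_mask_vtk(path, mask: DomainMask) -> None:
    with open(path, "w") as fh:
        _header(fh, "emboflow domain mask")
        _structured_points(fh, mask)
        fh.write("SCALARS label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mask.labels.ravel()[None], fmt="%d")


def write_field_vtk(path, mask: DomainMask, uc: np.ndarray, vc: np.ndarray) -> None:
    with open(path, "w") as fh:
        _header(fh, "emboflow velocity field")
        _structured_points(fh, mask)
        fh.write("VECTORS velocity float\n")
        flat = np.column_stack([uc.ravel(), vc.ravel(), np.zeros(uc.size)])
        np.savetxt(fh, flat, fmt="%.6g")


def write_trajectories_vtk(path, records) -> None:
    """Write clot trajectories as VTK polylines."""
    pts = []
    lines = []
    offset = 0
    for rec in records:
        n = len(rec.positions)
        pts.append(np.column_stack([rec.positions, np.zeros(n)]))
        lines.append([n] + list(range(offset, offset + n)))
        offset += n
    all_pts = np.vstack(pts) if pts else np.zeros((0, 3))
    with open(path, "w") as fh:
        _header(fh, "emboflow clot trajectories")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(all_pts)} float\n")
        np.savetxt(fh, all_pts, fmt="%.6g")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(v) for v in l) + "\n")
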