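"""Minimal legacy (ASCII) VTK structured-grid writer and reader.

Writes one STRUCTURED_GRID dataset per mesh block with POINT_DATA scalar
fields (cell data is averaged onto the nodes).  The reader parses exactly
the subset this writer emits — enough for round-trip checks and for
loading the exported fields into external visualization tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_structured", "read_vtk_structured"]


def write_vtk_structured(path, grid, block: int, cell_fields: dict) -> None:
    """Write node coordinates and node-averaged fields of one block."""
    blk = grid.blocks[block]
    nxp, nyp = blk.nx + 1, blk.ny + 1
    lines = [
        "# vtk DataFile Version 3.0",
        "hemoflow fields",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nxp} {nyp} 1",
        f"POINTS {nxp * nyp} double",
    ]
    # VTK expects x fastest
    for j in range(nyp):
        for i in range(nxp):
            lines.append(f"{blk.X[i, j]:.17g} {blk.Y[i, j]:.17g} 0")
    lines.append(f"POINT_DATA {nxp * nyp}")
    for name, q in cell_fields.items():
        nodal = grid.interpolate_to_nodes(np.asarray(q, dtype=float), block)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        for j in range(nyp):
            for i in range(nxp):
                lines.append(f"{nodal[i, j]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_structured(path):
    """Read a file written by :func:`write_vtk_structured`.

    Returns ``(points, fields)`` where points has shape (nx+1, ny+1, 2)
    and fields maps names to (nx+1, ny+1) arrays.
    """
    tok = Path(path).read_text().split("\n")
    it = iter(tok)
    dims = None
    for line in it:
        if line.startswith("DIMENSIONS"):
            dims = [int(v) for v in line.split()[1:]]
            break
    if dims is None:
        raise ValueError("not a structured-grid legacy VTK file")
    nxp, nyp, _ = dims
    npnts = nxp * nyp
    line = next(it)
    if not line.startswith("POINTS"):
        raise ValueError("expected POINTS")
    pts = np.empty((npnts, 3))
    for k in range(npnts):
        pts[k] = [float(v) for v in next(it).split()]
    points = pts[:, :2].reshape(nyp, nxp, 2).transpose(1, 0, 2)

    fields = {}
    for line in it:
        if line.startswith("SCALARS"):
            name = line.split()[1]
            next(it)  # LOOKUP_TABLE
            vals = np.array([float(next(it)) for _ in range(npnts)])
            fields[name] = vals.reshape(nyp, nxp).T
    return points, fields
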