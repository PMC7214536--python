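"""Legacy-VTK (ASCII) frame export: apical/basal polygons and lateral lines.

Each frame is a single ``vtk`` polydata file holding the apical and basal
cell polygons (cell data: cell id, relative volume change, cell state) and
the lateral vertex segments as lines.  Coordinates are written in μm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Monolayer, STATE_ABLATED, cell_volumes

__all__ = ["write_frame", "read_frame_polygons"]


def write_frame(m: Monolayer, path) -> None:
    mesh = m.mesh()
    P = mesh.positions() * m.length_unit
    V = cell_volumes(mesh, mesh.positions())
    dev = (V - mesh.cell_V0) / mesh.cell_V0

    polys = []
    poly_cell = []
    poly_layer = []
    for ci in range(len(mesh.cells)):
        polys.append(mesh.cell_apical_loop[ci])
        poly_cell.append(ci)
        poly_layer.append(0)
        polys.append(mesh.cell_basal_loop[ci])
        poly_cell.append(ci)
        poly_layer.append(1)
    lateral = [
        tuple(pq)
        for pq, k in zip(mesh.seg_p, mesh.seg_keys)
        if k[0] in ("VV", "VD", "WS")
    ]

    lines = [f"# vtk DataFile Version 3.0", f"epimech t={m.time:.3f} min", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(P)} float"]
    for p in P:
        lines.append(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
    size = sum(len(pl) + 1 for pl in polys)
    lines.append(f"POLYGONS {len(polys)} {size}")
    for pl in polys:
        lines.append(" ".join([str(len(pl))] + [str(int(p)) for p in pl]))
    lines.append(f"LINES {len(lateral)} {3 * len(lateral)}")
    for a, b in lateral:
        lines.append(f"2 {int(a)} {int(b)}")
    lines.append(f"CELL_DATA {len(polys) + len(lateral)}")
    lines.append("SCALARS cell_id int 1")
    lines.append("LOOKUP_TABLE default")
    for ci in poly_cell:
        lines.append(str(int(mesh.cells[ci])))
    lines.extend("-1" for _ in lateral)
    lines.append("SCALARS rel_volume_change float 1")
    lines.append("LOOKUP_TABLE default")
    for ci in poly_cell:
        lines.append(f"{dev[ci]:.6g}")
    lines.extend("0" for _ in lateral)
    lines.append("SCALARS ablated int 1")
    lines.append("LOOKUP_TABLE default")
    for ci in poly_cell:
        lines.append(str(int(m.cell_state[mesh.cells[ci]] == STATE_ABLATED)))
    lines.extend("0" for _ in lateral)
    Path(path).write_text("\n".join(lines) + "\n")


def read_frame_polygons(path):
    """Read back a frame written by :func:`write_frame` (for rendering).

    Returns ``(points, polygons, rel_volume_change, layer_flags)`` where
    ``layer_flags`` is 0 for apical and 1 for basal polygons.
    """
    text = Path(path).read_text().splitlines()
    it = iter(range(len(text)))
    pts = None
    polys: list[list[int]] = []
    dev = []
    i = 0
    while i < len(text):
        line = text[i]
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = np.array(
                [[float(x) for x in text[i + 1 + k].split()] for k in range(n)]
            )
            i += n
        elif line.startswith("POLYGONS"):
            n = int(line.split()[1])
            for k in range(n):
                vals = [int(x) for x in text[i + 1 + k].split()]
                polys.append(vals[1:])
            i += n
        elif line.startswith("SCALARS rel_volume_change"):
            i += 1  # LOOKUP_TABLE line
            dev = [float(text[i + 1 + k]) for k in range(len(polys))]
            i += len(polys)
        i += 1
    layer = np.array([k % 2 for k in range(len(polys))])
    return pts, polys, np.array(dev), layer
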