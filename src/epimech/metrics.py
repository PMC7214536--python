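"""Observables of a monolayer state: wound area, relative height, edge-cell
counts, and per-cell volume-deviation statistics."""

from __future__ import annotations

import numpy as np

from .geometry import (
    Monolayer,
    STATE_ABLATED,
    STATE_ALIVE,
    cell_volumes,
    polygon_area_xy,
)

__all__ = [
    "apical_wound_area",
    "relative_height",
    "wound_edge_counts",
    "volume_deviation_stats",
    "wound_perimeter_loops",
]


def apical_wound_area(m: Monolayer) -> float:
    """Projected apical wound area in μm² (shoelace; 0 once closed).

    The wound region is tiled by the (shrinking) ablated cells' apical
    polygons; the shoelace sum over those polygons equals the shoelace area
    of the ordered wound perimeter exactly (shared edges cancel pairwise).
    """
    if m.wound_closed:
        return 0.0
    mesh = m.mesh()
    P = mesh.positions()
    area = 0.0
    for ci, i in enumerate(mesh.cells):
        if m.cell_state[i] == STATE_ABLATED:
            area += polygon_area_xy(P, mesh.cell_apical_loop[ci])
    return area * m.length_unit**2


def wound_perimeter_loops(m: Monolayer) -> list[np.ndarray]:
    """Ordered apical wound-perimeter polyline(s), in μm coordinates."""
    mesh = m.mesh()
    if m.wound_closed or len(mesh.perim_seg_idx) == 0:
        return []
    P = mesh.positions()
    segs = [tuple(mesh.seg_p[s]) for s in mesh.perim_seg_idx]
    adj: dict[int, list[int]] = {}
    for a, b in segs:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(s)) for s in segs}
    loops = []
    while unused:
        a, b = sorted(unused)[0]
        loop = [a, b]
        unused.discard((a, b))
        while True:
            nxt = [
                v
                for v in adj[loop[-1]]
                if tuple(sorted((loop[-1], v))) in unused
            ]
            if not nxt:
                break
            loop.append(nxt[0])
            unused.discard(tuple(sorted((loop[-2], loop[-1]))))
        loops.append(P[loop] * m.length_unit)
    return loops


def wound_edge_counts(m: Monolayer) -> tuple[int, int]:
    """(number of live cells at the wound edge, number of apical perimeter
    junction segments); (0, 0) once the wound has closed."""
    mesh = m.mesh()
    if m.wound_closed:
        return 0, 0
    return len(mesh.edge_cell_ids), len(mesh.perim_seg_idx)


def relative_height(m: Monolayer, reference_height_um: float | None = None) -> float:
    """1 − (apical indentation depth / reference height), dimensionless.

    The depth is the apico-basal distance between a reference apical level —
    the 95th percentile of apical z over material within an annulus 2–4
    cell diameters away from the wound centre (a deterministic surrogate of
    fitting a line across the highest apical points either side of the
    wound) — and the mean apical z of the wound perimeter.  An unwounded
    flat monolayer reports exactly 1.
    """
    if reference_height_um is None:
        reference_height_um = m.height * m.length_unit
    mesh = m.mesh()
    if m.wound_closed or len(mesh.perim_seg_idx) == 0:
        # wound closed or never wounded: indentation measured at the (former)
        # wound centre is not defined; report the patch-centre apical level
        if not np.any(m.cell_state == STATE_ABLATED) and m.wound_max_area == 0.0:
            return 1.0
        perim_pts = None
    else:
        perim_pts = mesh.perim_pt_ids
    P = mesh.positions()
    alive = np.flatnonzero(m.cell_state == STATE_ALIVE)
    apical_nodes = P[alive]  # apical node points coincide with node ids
    if perim_pts is None:
        # depth at the healed centre relative to the far field
        centre = apical_nodes[:, :2].mean(axis=0)
        z_wound = None
    else:
        pp = P[perim_pts]
        centre = pp[:, :2].mean(axis=0)
        z_wound = float(pp[:, 2].mean())
    diam = 2.0 * np.sqrt(m.init_mean_cell_area / np.pi)
    r = np.linalg.norm(apical_nodes[:, :2] - centre, axis=1)
    ann = (r >= 2.0 * diam) & (r <= 4.0 * diam)
    ref_z = float(np.percentile(apical_nodes[ann if ann.any() else slice(None), 2], 95))
    if z_wound is None:
        inner = r <= 1.5 * diam
        z_wound = float(apical_nodes[inner if inner.any() else slice(None), 2].min())
    depth = max(ref_z - z_wound, 0.0) * m.length_unit
    return 1.0 - depth / reference_height_um


def volume_deviation_stats(m: Monolayer) -> tuple[float, float]:
    """(mean, max) of |V − V0| / V0 over alive, non-ablated cells."""
    mesh = m.mesh()
    V = cell_volumes(mesh, mesh.positions())
    alive = m.cell_state[mesh.cells] == STATE_ALIVE
    if not alive.any():
        return 0.0, 0.0
    dev = np.abs(V[alive] - mesh.cell_V0[alive]) / mesh.cell_V0[alive]
    return float(dev.mean()), float(dev.max())
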