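"""Connectivity updates: aspect-ratio-gated Delaunay flips and cell removal.

After each converged step the apical and basal layers are re-triangulated
independently by local edge flips toward the Delaunay criterion.  A flip is
accepted only if the worst post-flip triangle aspect ratio r satisfies
``r_new < (1 + tol_r) · r_old``; at ``tol_r = 0`` the pass reduces to the
standard (Lawson) Delaunay flip algorithm, while ``tol_r > 0`` tolerates
mildly worse, stretched triangles, which is what lets wound-edge cells
intercalate.  Because the two layers flip independently, their edge sets
may disagree; every disagreement must remain a pairable single-flip quad
(stitched by one intermediate vertex, see :mod:`epimech.geometry`), and a
flip that would break pairability is deferred.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np

from .geometry import (
    GeometryError,
    LAYER_APICAL,
    LAYER_BASAL,
    Monolayer,
    STATE_REMOVED,
    edge_tri_map,
    edges_of,
    find_mismatches,
    tri_key,
)

__all__ = [
    "RemeshSettings",
    "propose_flips",
    "apply_connectivity_change",
    "reconcile_intermediate_vertices",
    "remesh_step",
    "remove_cell_node",
]


@dataclass
class RemeshSettings:
    """tol_r: aspect-ratio tolerance of the flip acceptance rule (0 recovers
    plain Delaunay); max_flips bounds flip cycling; force_equal_layers keeps
    apical and basal triangulations identical (pure-prism model, no
    intermediate vertices)."""

    tol_r: float = 0.3
    max_flips: int = 200
    force_equal_layers: bool = False
    #: wound-perimeter junctions shorter than this fraction of the initial
    #: mean junction length trigger a forced intercalation (T1), the
    #: junction-collapse rule of classical vertex models
    junction_collapse_fraction: float = 0.25

    def __post_init__(self):
        if self.tol_r < 0:
            raise ValueError("tol_r must be non-negative")
        if not 0.0 <= self.junction_collapse_fraction < 1.0:
            raise ValueError("junction_collapse_fraction must lie in [0, 1)")


def _ccw(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _incircle(a, b, c, d) -> float:
    """> 0 iff d lies strictly inside the circumcircle of CCW triangle abc."""
    ax, ay = a[0] - d[0], a[1] - d[1]
    bx, by = b[0] - d[0], b[1] - d[1]
    cx, cy = c[0] - d[0], c[1] - d[1]
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    return float(
        ax * (by * c2 - b2 * cy) - ay * (bx * c2 - b2 * cx) + a2 * (bx * cy - by * cx)
    )


def _aspect(xy, t) -> float:
    p = xy[list(t)]
    e = np.array(
        [
            np.linalg.norm(p[1] - p[0]),
            np.linalg.norm(p[2] - p[1]),
            np.linalg.norm(p[0] - p[2]),
        ]
    )
    if e.min() <= 0:
        return float("inf")
    return float(e.max() / e.min())


def propose_flips(
    tris: list[tuple[int, int, int]],
    xy: np.ndarray,
    tol_r: float,
    *,
    other_tris: list[tuple[int, int, int]] | None = None,
    max_flips: int = 200,
):
    """Flip edges toward the Delaunay criterion, gated by aspect ratio.

    ``xy`` are the layer's node positions projected along the apico-basal
    axis.  If ``other_tris`` is given (the opposite layer), flips that would
    leave the two layers' disagreement unpairable are deferred.  Returns
    ``(new_tris, flipped_edges)``; raises GeometryError when the flip budget
    is exhausted without reaching a fixed point (flip cycling).
    """
    tris = [tri_key(t) for t in tris]
    flips: list[tuple[int, int]] = []
    for _ in range(max_flips + 1):
        emap = edge_tri_map(tris)
        flipped = False
        for e in sorted(emap):
            pair = emap[e]
            if len(pair) != 2:
                continue
            i, j = e
            t1, t2 = pair
            k = next(v for v in t1 if v not in e)
            l = next(v for v in t2 if v not in e)
            pi, pj, pk, pl = xy[i], xy[j], xy[k], xy[l]
            # strict convexity of the quad (k i l j): flip must be valid
            if _ccw(pk, pl, pi) * _ccw(pk, pl, pj) >= 0:
                continue
            if _ccw(pi, pj, pk) * _ccw(pi, pj, pl) >= 0:
                continue
            # Delaunay (in-circle) candidate test on CCW-oriented t1
            abc = (pi, pj, pk) if _ccw(pi, pj, pk) > 0 else (pj, pi, pk)
            if _incircle(*abc, pl) <= 1e-14:
                continue
            r_old = max(_aspect(xy, t1), _aspect(xy, t2))
            new1, new2 = tri_key((i, k, l)), tri_key((j, k, l))
            r_new = max(_aspect(xy, new1), _aspect(xy, new2))
            if r_new >= (1.0 + tol_r) * r_old * (1.0 + 1e-12):
                continue
            cand = [t for t in tris if t not in (t1, t2)] + [new1, new2]
            if other_tris is not None:
                _, unpaired = find_mismatches(cand, other_tris)
                if unpaired:
                    continue  # defer: would break apico-basal pairability
            tris = cand
            flips.append(e)
            flipped = True
            break
        if not flipped:
            return sorted(tris), flips
    raise GeometryError(f"flip budget ({max_flips}) exhausted; flip cycling suspected")


def apply_connectivity_change(
    m: Monolayer, layer: str, new_tris: list[tuple[int, int, int]]
) -> None:
    """Install a new triangulation for one layer.

    Vertices of removed triangles disappear (their interpolated positions
    are re-derived), segments of changed faces are reborn stress-free at
    their current length, and everything untouched keeps its rest-length
    state — all of which is handled by keyed state in the mesh rebuild.
    Raises GeometryError if the change would leave the layers unpairable.
    """
    new_tris = sorted(tri_key(t) for t in new_tris)
    other = m.tri_b if layer == LAYER_APICAL else m.tri_a
    a, b = (new_tris, other) if layer == LAYER_APICAL else (other, new_tris)
    _, unpaired = find_mismatches(a, b)
    if unpaired:
        raise GeometryError(f"connectivity change leaves unpairable edges: {unpaired[:4]}")
    if layer == LAYER_APICAL:
        m.tri_a = new_tris
    else:
        m.tri_b = new_tris
    m.invalidate_mesh()


def reconcile_intermediate_vertices(m: Monolayer):
    """Create/destroy intermediate vertices to stitch layer disagreements.

    The stitching itself is carried out during the mesh build (one
    intermediate vertex per pairable flip quad, born at the mid-height
    average of the four bridged vertices; removed when the layers agree
    again).  This triggers the rebuild and returns the mismatch records.
    """
    m.invalidate_mesh()
    return m.mesh().mismatches


def remesh_step(m: Monolayer, settings: RemeshSettings):
    """Re-triangulate both layers after a converged step.

    Returns a list of T1 events ``(layer, flipped_edge)``.  With
    ``force_equal_layers`` the apical result is imposed on the basal layer
    as well, so no intermediate vertices can ever arise.
    """
    events: list[tuple[str, tuple[int, int]]] = []
    xy_a = m.apical[:, :2]
    xy_b = m.basal[:, :2]
    if settings.force_equal_layers:
        new_a, fl = propose_flips(
            m.tri_a, xy_a, settings.tol_r, max_flips=settings.max_flips
        )
        events += [(LAYER_APICAL, e) for e in fl]
        if fl:
            m.tri_a = new_a
            m.tri_b = list(new_a)
            m.invalidate_mesh()
        return events
    new_a, fl_a = propose_flips(
        m.tri_a, xy_a, settings.tol_r, other_tris=m.tri_b, max_flips=settings.max_flips
    )
    if fl_a:
        m.tri_a = new_a
        m.invalidate_mesh()
    events += [(LAYER_APICAL, e) for e in fl_a]
    new_b, fl_b = propose_flips(
        m.tri_b, xy_b, settings.tol_r, other_tris=m.tri_a, max_flips=settings.max_flips
    )
    if fl_b:
        m.tri_b = new_b
        m.invalidate_mesh()
    events += [(LAYER_BASAL, e) for e in fl_b]
    events += collapse_wound_junctions(m, settings)
    return events


def collapse_wound_junctions(m: Monolayer, settings: RemeshSettings):
    """Force an intercalation where an apical wound-perimeter junction has
    collapsed.

    When the purse-string shortens the junction between a wound-edge cell
    and a degraded cell below ``junction_collapse_fraction`` of the initial
    mean junction length, the cell is squeezed off the wound edge: the
    corresponding node edge is flipped so its two flanking cells become
    neighbours (the junction-collapse T1 of classical vertex models).  At
    most one collapse per call, the shortest first; flips that would be
    geometrically invalid or leave the layers unpairable are deferred.
    """
    if np.isnan(m.init_mean_junction_len):
        return []
    mesh = m.mesh()
    if len(mesh.perim_seg_idx) == 0:
        return []
    P = mesh.positions()
    lref = settings.junction_collapse_fraction * m.init_mean_junction_len
    perim = mesh.perim_seg_idx
    lengths = np.linalg.norm(P[mesh.seg_p[perim, 1]] - P[mesh.seg_p[perim, 0]], axis=1)
    order = np.argsort(lengths, kind="stable")
    xy = m.apical[:, :2]
    emap = edge_tri_map(m.tri_a)
    for o in order:
        if lengths[o] >= lref:
            break
        key = mesh.seg_keys[int(perim[o])]
        e = (key[1], key[2])
        pair = emap.get(e, [])
        if len(pair) != 2:
            continue
        i, j = e
        a = next(v for v in pair[0] if v not in e)
        b = next(v for v in pair[1] if v not in e)
        if _ccw(xy[a], xy[b], xy[i]) * _ccw(xy[a], xy[b], xy[j]) >= 0:
            continue
        if _ccw(xy[i], xy[j], xy[a]) * _ccw(xy[i], xy[j], xy[b]) >= 0:
            continue
        cand = sorted(
            [t for t in m.tri_a if t not in pair]
            + [tri_key((i, a, b)), tri_key((j, a, b))]
        )
        _, unpaired = find_mismatches(cand, m.tri_b)
        if unpaired:
            continue
        m.tri_a = cand
        m.invalidate_mesh()
        return [(LAYER_APICAL, e)]
    return []


# ---------------------------------------------------------------------------
# cell removal (degraded wound cells)


def _cavity_cycle(tris, node: int) -> list[int]:
    """Ordered boundary cycle of the triangles incident to ``node``."""
    incident = [t for t in tris if node in t]
    nxt: dict[int, int] = {}
    by_edge: dict[int, list] = {}
    for t in incident:
        for v in t:
            if v != node:
                by_edge.setdefault(v, []).append(t)
    start = next(v for v in incident[0] if v != node)
    cycle = [start]
    current = incident[0]
    entry = start
    for _ in range(len(incident) + 1):
        exit_v = next(v for v in current if v != node and v != entry)
        if exit_v == start:
            break
        cycle.append(exit_v)
        nxt_tris = [t for t in by_edge[exit_v] if t is not current]
        if not nxt_tris:
            raise GeometryError(f"open cavity around node {node}")
        current = nxt_tris[0]
        entry = exit_v
    if len(cycle) != len(incident):
        raise GeometryError(f"cavity around node {node} is not a single cycle")
    return cycle


def _ear_clip(cycle: list[int], xy: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple polygon (node-id cycle) by ear clipping."""
    poly = list(cycle)
    pts = {v: xy[v] for v in poly}
    # ensure CCW
    arr = np.array([pts[v] for v in poly])
    if (np.dot(arr[:, 0], np.roll(arr[:, 1], -1)) - np.dot(arr[:, 1], np.roll(arr[:, 0], -1))) < 0:
        poly.reverse()
    out = []
    guard = 0
    while len(poly) > 3 and guard < 10000:
        guard += 1
        n = len(poly)
        best = None
        for t in range(n):
            a, b, c = poly[(t - 1) % n], poly[t], poly[(t + 1) % n]
            if _ccw(pts[a], pts[b], pts[c]) <= 0:
                continue  # reflex
            tri_pts = (pts[a], pts[b], pts[c])
            if any(
                _point_in_tri(pts[v], *tri_pts)
                for v in poly
                if v not in (a, b, c)
            ):
                continue
            # prefer the best-shaped ear for mesh quality
            q = _aspect(xy, (a, b, c))
            if best is None or q < best[0]:
                best = (q, t, (a, b, c))
        if best is None:
            raise GeometryError("ear clipping failed (non-simple cavity polygon)")
        _, t, ear = best
        out.append(tri_key(ear))
        del poly[t]
    out.append(tri_key(tuple(poly)))
    return out


def _point_in_tri(p, a, b, c) -> bool:
    d1, d2, d3 = _ccw(a, b, p), _ccw(b, c, p), _ccw(c, a, p)
    return (d1 >= 0 and d2 >= 0 and d3 >= 0) or (d1 <= 0 and d2 <= 0 and d3 <= 0)


def _align_layers(tri_a, tri_b, xy_a, xy_b, budget: int = 50):
    """Greedy flips that restore single-flip pairability between layers."""
    for _ in range(budget):
        _, unpaired = find_mismatches(tri_a, tri_b)
        if not unpaired:
            return tri_a, tri_b
        progressed = False
        for layer, e in unpaired:
            tris = tri_a if layer == LAYER_APICAL else tri_b
            other = tri_b if layer == LAYER_APICAL else tri_a
            xy = xy_a if layer == LAYER_APICAL else xy_b
            emap = edge_tri_map(tris)
            pair = emap.get(e, [])
            if len(pair) != 2:
                continue
            i, j = e
            k = next(v for v in pair[0] if v not in e)
            l = next(v for v in pair[1] if v not in e)
            diag = (k, l) if k < l else (l, k)
            if diag not in edges_of(other):
                continue
            if _ccw(xy[k], xy[l], xy[i]) * _ccw(xy[k], xy[l], xy[j]) >= 0:
                continue
            new = [t for t in tris if t not in pair] + [tri_key((i, k, l)), tri_key((j, k, l))]
            if layer == LAYER_APICAL:
                tri_a = sorted(new)
            else:
                tri_b = sorted(new)
            progressed = True
            break
        if not progressed:
            raise GeometryError(f"cannot restore apico-basal pairability: {unpaired[:4]}")
    raise GeometryError("layer alignment budget exhausted")


def remove_cell_node(m: Monolayer, node: int) -> None:
    """Remove a degraded cell: delete its node from both triangulations and
    re-triangulate the cavities (identically in both layers when their
    boundary cycles agree, else independently followed by re-alignment)."""
    cyc_a = _cavity_cycle(m.tri_a, node)
    cyc_b = _cavity_cycle(m.tri_b, node)
    xy_a = m.apical[:, :2]
    xy_b = m.basal[:, :2]
    rest_a = [t for t in m.tri_a if node not in t]
    rest_b = [t for t in m.tri_b if node not in t]

    def _same_cycle(c1, c2) -> bool:
        if len(c1) != len(c2):
            return False
        if set(c1) != set(c2):
            return False
        n = len(c1)
        for rev in (c2, c2[::-1]):
            for s in range(n):
                if all(c1[t] == rev[(s + t) % n] for t in range(n)):
                    return True
        return False

    if _same_cycle(cyc_a, cyc_b):
        patch = _ear_clip(cyc_a, xy_a)
        tri_a = sorted(rest_a + patch)
        tri_b = sorted(rest_b + patch)
    else:
        tri_a = sorted(rest_a + _ear_clip(cyc_a, xy_a))
        tri_b = sorted(rest_b + _ear_clip(cyc_b, xy_b))
    _, unpaired = find_mismatches(tri_a, tri_b)
    if unpaired:
        try:
            tri_a, tri_b = _align_layers(tri_a, tri_b, xy_a, xy_b)
        except GeometryError:
            # last resort: collapse the apico-basal topology difference by
            # imposing the apical connectivity on both layers (resolves all
            # pending spatial T1s at once); logged as an exceptional event
            logging.getLogger("epimech").warning(
                "node %d removal: unpairable layers, equalising connectivity", node
            )
            tri_b = list(tri_a)
    m.tri_a = tri_a
    m.tri_b = tri_b
    m.cell_state[node] = STATE_REMOVED
    m.is_fixed[node] = True
    m.V0[node] = np.nan
    m.invalidate_mesh()
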