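"""Two-layer prism-cell geometry for the hybrid cell-centre/vertex model.

The monolayer is described by cell-centre *nodes* carrying an apical and a
basal position, one *vertex* per triangle of each layer's Delaunay-style
triangulation (located at the triangle barycentre and, away from the wound,
interpolated — not independent unknowns), and bar *segments* forming two
coupled networks (nodal and vertex).  Cells are prism-like polyhedra bounded
by the apical and basal vertex loops around their node; when the two layers
disagree topologically, free *intermediate vertices* stitch the lateral
surface.

All coordinates held in :class:`Monolayer` are in model units (μm divided by
``length_unit``); the I/O surface of the package speaks μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "Monolayer",
    "Mesh",
    "GeometryError",
    "build_monolayer",
    "build_mesh",
    "interpolate_vertices",
    "cell_volume",
    "triangle_aspect_ratio",
    "mesh_audit",
]

# cell states (per node; ring nodes carry no cell)
STATE_NONE = 0
STATE_ALIVE = 1
STATE_ABLATED = 2
STATE_REMOVED = 3

LAYER_APICAL = "A"
LAYER_BASAL = "B"

#: Stiffness multiplier applied to segments fully interior to ablated cells.
ABLATED_STIFFNESS_SCALE = 0.01

#: Minimum number of ablated parent nodes for a wound-edge vertex to be
#: released from the barycentric constraint (3 disables relaxation).
RELAX_MIN_ABLATED = 2

# segment scheduling codes
SCHED_NONE = 0
SCHED_APICAL = 1  # apical purse-string (wound perimeter, apical layer)
SCHED_LATERAL = 2  # lateral contractility (wound-edge lateral faces)


class GeometryError(RuntimeError):
    """Degenerate or topologically inconsistent mesh input."""


def triangle_aspect_ratio(p0, p1, p2) -> float:
    """Aspect ratio of a triangle: longest edge over shortest edge (>= 1).

    Monotone in "stretchedness" and 1 exactly for equilateral triangles;
    zero-length shortest edge returns ``inf``.
    """
    p0, p1, p2 = (np.asarray(p) for p in (p0, p1, p2))
    e = np.array(
        [np.linalg.norm(p1 - p0), np.linalg.norm(p2 - p1), np.linalg.norm(p0 - p2)]
    )
    if e.min() <= 0.0:
        return float("inf")
    return float(e.max() / e.min())


@dataclass
class MismatchRecord:
    """A single apico-basal connectivity disagreement (spatial T1).

    The apical layer holds edge ``(i, j)`` (triangles ijk and ijl) while the
    basal layer holds the flipped edge ``(k, l)`` (triangles kli and klj).
    One intermediate vertex, keyed by the four participating cells, stitches
    the lateral surface of the region.
    """

    quad: tuple[int, int, int, int]  # sorted node ids
    apical_edge: tuple[int, int]
    basal_edge: tuple[int, int]

    @property
    def apical_tris(self) -> list[tuple[int, int, int]]:
        i, j = self.apical_edge
        k, l = self.basal_edge
        return [tuple(sorted((i, j, k))), tuple(sorted((i, j, l)))]

    @property
    def basal_tris(self) -> list[tuple[int, int, int]]:
        i, j = self.apical_edge
        k, l = self.basal_edge
        return [tuple(sorted((k, l, i))), tuple(sorted((k, l, j)))]


@dataclass
class Monolayer:
    """Full simulation state.

    Node positions are (N, 3) arrays in model units.  Triangulations are
    lists of sorted node triples; orientation is derived from the projected
    positions whenever loops are built.  ``seg_state`` maps segment keys to
    ``[rest_length, reference_length]`` pairs so that rest lengths survive
    connectivity changes of unrelated parts of the mesh.
    """

    apical: np.ndarray
    basal: np.ndarray
    is_ring: np.ndarray
    is_fixed: np.ndarray
    cell_state: np.ndarray
    V0: np.ndarray
    tri_a: list[tuple[int, int, int]]
    tri_b: list[tuple[int, int, int]]
    height: float
    length_unit: float
    inter_pos: dict = field(default_factory=dict)
    relaxed_pos: dict = field(default_factory=dict)
    seg_state: dict = field(default_factory=dict)
    time: float = 0.0
    wound_max_area: float = 0.0
    wound_closed: bool = False
    init_mean_cell_area: float = float("nan")
    init_mean_junction_len: float = float("nan")
    ablated_scale: float = ABLATED_STIFFNESS_SCALE
    _mesh: "Mesh | None" = field(default=None, repr=False)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.apical)

    @property
    def cell_ids(self) -> np.ndarray:
        """Nodes carrying a live or ablated cell (in id order)."""
        return np.flatnonzero(
            (self.cell_state == STATE_ALIVE) | (self.cell_state == STATE_ABLATED)
        )

    def invalidate_mesh(self) -> None:
        self._mesh = None

    def mesh(self) -> "Mesh":
        if self._mesh is None:
            self._mesh = build_mesh(self)
        return self._mesh

    def copy(self) -> "Monolayer":
        return Monolayer(
            apical=self.apical.copy(),
            basal=self.basal.copy(),
            is_ring=self.is_ring.copy(),
            is_fixed=self.is_fixed.copy(),
            cell_state=self.cell_state.copy(),
            V0=self.V0.copy(),
            tri_a=list(self.tri_a),
            tri_b=list(self.tri_b),
            height=self.height,
            length_unit=self.length_unit,
            inter_pos={k: v.copy() for k, v in self.inter_pos.items()},
            relaxed_pos={k: v.copy() for k, v in self.relaxed_pos.items()},
            seg_state={k: list(v) for k, v in self.seg_state.items()},
            time=self.time,
            wound_max_area=self.wound_max_area,
            wound_closed=self.wound_closed,
            init_mean_cell_area=self.init_mean_cell_area,
            init_mean_junction_len=self.init_mean_junction_len,
            ablated_scale=self.ablated_scale,
        )


# ---------------------------------------------------------------------------
# triangulation helpers


def tri_key(tri) -> tuple[int, int, int]:
    return tuple(sorted(int(v) for v in tri))


def edges_of(tris) -> set[tuple[int, int]]:
    out = set()
    for a, b, c in tris:
        out.add((a, b) if a < b else (b, a))
        out.add((b, c) if b < c else (c, b))
        out.add((a, c) if a < c else (c, a))
    return out


def edge_tri_map(tris) -> dict[tuple[int, int], list[tuple[int, int, int]]]:
    out: dict[tuple[int, int], list] = {}
    for t in tris:
        a, b, c = t
        for e in ((a, b), (b, c), (a, c)):
            e = e if e[0] < e[1] else (e[1], e[0])
            out.setdefault(e, []).append(t)
    return out


def find_mismatches(tri_a, tri_b):
    """Pair apical-only edges with their flipped basal counterparts.

    Returns ``(records, unpaired)`` where ``unpaired`` lists edges in the
    symmetric difference of the two layers' edge sets that do not form a
    single-flip quad.
    """
    ea, eb = edges_of(tri_a), edges_of(tri_b)
    map_a, map_b = edge_tri_map(tri_a), edge_tri_map(tri_b)
    records, unpaired = [], []
    for e in sorted(ea - eb):
        tris = map_a.get(e, [])
        if len(tris) != 2:
            unpaired.append((LAYER_APICAL, e))
            continue
        i, j = e
        thirds = sorted(set(tris[0]) ^ set(tris[1]))
        if len(thirds) != 2:
            unpaired.append((LAYER_APICAL, e))
            continue
        k, l = thirds
        fe = (k, l)
        btris = map_b.get(fe, [])
        want = {tri_key((k, l, i)), tri_key((k, l, j))}
        if fe in eb - ea and len(btris) == 2 and {tri_key(t) for t in btris} == want:
            records.append(
                MismatchRecord(quad=tuple(sorted((i, j, k, l))), apical_edge=e, basal_edge=fe)
            )
        else:
            unpaired.append((LAYER_APICAL, e))
    paired_basal = {r.basal_edge for r in records}
    for e in sorted(eb - ea):
        if e not in paired_basal:
            unpaired.append((LAYER_BASAL, e))
    return records, unpaired


def _fan_around(node: int, tris, xy: np.ndarray):
    """Ordered (CCW in projection) fan of triangles around an interior node.

    Returns ``(ordered_tris, neighbours)`` where ``neighbours[t]`` is the
    node shared by ``ordered_tris[t]`` and ``ordered_tris[t+1]`` (the cell
    adjacent across that loop edge).
    """
    incident = [t for t in tris if node in t]
    if len(incident) < 3:
        raise GeometryError(f"node {node} has fewer than 3 incident triangles")
    # adjacency via shared (node, x) edges
    by_edge: dict[int, list] = {}
    for t in incident:
        for v in t:
            if v != node:
                by_edge.setdefault(v, []).append(t)
    for v, ts in by_edge.items():
        if len(ts) != 2:
            raise GeometryError(f"open fan around node {node} (edge to {v})")
    start = incident[0]
    order = [start]
    nbrs: list[int] = []
    entry = next(v for v in start if v != node)
    current = start
    for _ in range(len(incident) + 1):
        exit_v = next(v for v in current if v != node and v != entry)
        nbrs.append(exit_v)
        t2 = next(t for t in by_edge[exit_v] if t is not current)
        if t2 is start:
            break
        order.append(t2)
        current = t2
        entry = exit_v
    if len(order) != len(incident):
        raise GeometryError(f"fan around node {node} is not a single cycle")
    # orient CCW by the signed area of the barycentre polygon
    bary = np.array([xy[list(t)].mean(axis=0) for t in order])
    x, y = bary[:, 0], bary[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if area2 < 0.0:
        order = [order[0]] + order[:0:-1]
        nbrs = nbrs[::-1]
    return order, nbrs


# ---------------------------------------------------------------------------
# mesh build


class Mesh:
    """Derived, flat-array view of a :class:`Monolayer` for assembly.

    Holds the point table (nodes, vertices, intermediate vertices, cell
    midpoints), the linear map from free degrees of freedom to point
    positions (``P = A u + b``, with Dirichlet data folded into ``b``), the
    segment table with rest-length state, and per-cell tetrahedral
    decompositions for volumes.
    """

    def __init__(self):
        self.state: Monolayer | None = None
        self.n_pts = 0
        self.pt_node_a: np.ndarray | None = None
        self.pt_node_b: np.ndarray | None = None
        self.pt_vert: dict = {}
        self.pt_inter: dict = {}
        self.pt_mid: dict = {}
        self.relaxed: set = set()
        self.mismatches: list[MismatchRecord] = []
        # dofs
        self.dof_keys: list = []
        self.A: sp.csr_matrix | None = None
        self.b: np.ndarray | None = None
        # segments
        self.seg_keys: list = []
        self.seg_p = np.zeros((0, 2), dtype=np.int64)
        self.seg_is_vertex = np.zeros(0, dtype=bool)
        self.seg_scale = np.zeros(0)
        self.seg_sched = np.zeros(0, dtype=np.int8)
        self.L = np.zeros(0)
        self.L0 = np.zeros(0)
        # cells
        self.cells = np.zeros(0, dtype=np.int64)  # node ids
        self.cell_V0 = np.zeros(0)
        self.cell_penalty = np.zeros(0, dtype=bool)
        self.cell_apical_loop: list = []  # per cell: list of point ids
        self.cell_basal_loop: list = []
        self.tets = np.zeros((0, 4), dtype=np.int64)
        self.tet_cell = np.zeros(0, dtype=np.int64)
        self.faces: list = []  # (cell_idx, (p0, p1, p2)) triangles, outward
        self.cell_pts: np.ndarray | None = None  # (ncell, W) padded with dummy
        self.tet_slot: np.ndarray | None = None  # (ntet, 4) slot of corner in cell_pts
        # wound
        self.perim_seg_idx = np.zeros(0, dtype=np.int64)
        self.perim_pt_ids: np.ndarray = np.zeros(0, dtype=np.int64)
        self.edge_cell_ids: np.ndarray = np.zeros(0, dtype=np.int64)

    # -- positions and dofs ------------------------------------------------
    def gather_u(self) -> np.ndarray:
        m = self.state
        u = np.zeros(3 * len(self.dof_keys))
        for s, key in enumerate(self.dof_keys):
            kind = key[0]
            if kind == "NA":
                u[3 * s : 3 * s + 3] = m.apical[key[1]]
            elif kind == "NB":
                u[3 * s : 3 * s + 3] = m.basal[key[1]]
            elif kind == "RV":
                u[3 * s : 3 * s + 3] = m.relaxed_pos[(key[1], key[2])]
            else:  # IV
                u[3 * s : 3 * s + 3] = m.inter_pos[key[1]]
        return u

    def scatter_u(self, u: np.ndarray) -> None:
        m = self.state
        for s, key in enumerate(self.dof_keys):
            kind = key[0]
            val = u[3 * s : 3 * s + 3]
            if kind == "NA":
                m.apical[key[1]] = val
            elif kind == "NB":
                m.basal[key[1]] = val
            elif kind == "RV":
                m.relaxed_pos[(key[1], key[2])] = val.copy()
            else:
                m.inter_pos[key[1]] = val.copy()

    def positions(self, u: np.ndarray | None = None) -> np.ndarray:
        if u is None:
            u = self.gather_u()
        return (self.A @ u + self.b).reshape(-1, 3)

    def sync_rest_lengths(self) -> None:
        """Write the mesh's rest-length arrays back into the state registry."""
        m = self.state
        for k, L, L0 in zip(self.seg_keys, self.L, self.L0):
            m.seg_state[k] = [float(L), float(L0)]


def _segment_parent_states(key, cell_state) -> list[int]:
    kind = key[0]
    if kind in ("NA", "NB", "ND", "VA", "VB", "VD"):
        return [cell_state[key[1]], cell_state[key[2]]]
    if kind == "NV":
        return [cell_state[key[1]]]
    if kind == "VV":
        return [cell_state[v] for v in key[1]]
    if kind == "WS":
        return [cell_state[v] for v in key[1]]
    raise KeyError(kind)


def build_mesh(m: Monolayer) -> Mesh:  # noqa: C901 - one long, linear build
    mesh = Mesh()
    mesh.state = m
    N = m.n_nodes
    cs = m.cell_state
    present = cs != STATE_REMOVED  # nodes participating in the triangulations

    tri_a = [tri_key(t) for t in m.tri_a]
    tri_b = [tri_key(t) for t in m.tri_b]
    set_a, set_b = set(tri_a), set(tri_b)
    ea, eb = edges_of(tri_a), edges_of(tri_b)
    map_a, map_b = edge_tri_map(tri_a), edge_tri_map(tri_b)

    records, unpaired = find_mismatches(tri_a, tri_b)
    if unpaired:
        raise GeometryError(f"unpairable apico-basal connectivity: {unpaired[:4]}")
    mesh.mismatches = records
    rec_by_aedge = {r.apical_edge: r for r in records}
    rec_by_bedge = {r.basal_edge: r for r in records}

    # wound-edge (relaxed) vertices: vertices on the wound side of the
    # perimeter (parent triangle dominated by ablated cells) are released
    # from the barycentric constraint to avoid zig-zag artifacts; vertices
    # with a live majority stay interpolated so that wound-edge tensions
    # keep acting on the surviving cells' centres
    def _is_wound_edge_tri(t) -> bool:
        sts = [cs[v] for v in t]
        n_abl = sts.count(STATE_ABLATED)
        return n_abl >= RELAX_MIN_ABLATED and STATE_ALIVE in sts

    relaxed = set()
    for t in tri_a:
        if _is_wound_edge_tri(t):
            relaxed.add((LAYER_APICAL, t))
    for t in tri_b:
        if _is_wound_edge_tri(t):
            relaxed.add((LAYER_BASAL, t))
    mesh.relaxed = relaxed

    # ---- points ----------------------------------------------------------
    pt_positions: list[np.ndarray] = []  # build-time positions, for births
    mesh.pt_node_a = np.arange(N)
    mesh.pt_node_b = np.arange(N) + N
    pt_positions.extend(list(m.apical))
    pt_positions.extend(list(m.basal))
    idx = 2 * N

    xy_a = m.apical[:, :2]
    xy_b = m.basal[:, :2]

    def _bary(layer, t):
        arr = m.apical if layer == LAYER_APICAL else m.basal
        return arr[list(t)].mean(axis=0)

    for t in tri_a:
        key = (LAYER_APICAL, t)
        mesh.pt_vert[key] = idx
        if key in relaxed:
            if key not in m.relaxed_pos:
                m.relaxed_pos[key] = _bary(*key).copy()
            pt_positions.append(m.relaxed_pos[key])
        else:
            pt_positions.append(_bary(*key))
        idx += 1
    for t in tri_b:
        key = (LAYER_BASAL, t)
        mesh.pt_vert[key] = idx
        if key in relaxed:
            if key not in m.relaxed_pos:
                m.relaxed_pos[key] = _bary(*key).copy()
            pt_positions.append(m.relaxed_pos[key])
        else:
            pt_positions.append(_bary(*key))
        idx += 1

    current_quads = {r.quad for r in records}
    for q in sorted(m.inter_pos.keys()):
        if q not in current_quads:
            del m.inter_pos[q]
    for key in sorted(m.relaxed_pos.keys()):
        if key not in relaxed:
            del m.relaxed_pos[key]

    for r in records:
        if r.quad not in m.inter_pos:
            # born at the mid-height average of the four bridged vertices
            pts = [
                _bary(LAYER_APICAL, t) for t in r.apical_tris
            ] + [_bary(LAYER_BASAL, t) for t in r.basal_tris]
            m.inter_pos[r.quad] = np.mean(pts, axis=0)
        mesh.pt_inter[r.quad] = idx
        pt_positions.append(m.inter_pos[r.quad])
        idx += 1

    cell_ids = m.cell_ids
    for i in cell_ids:
        mesh.pt_mid[int(i)] = idx
        pt_positions.append(0.5 * (m.apical[i] + m.basal[i]))
        idx += 1
    dummy = idx
    pt_positions.append(np.zeros(3))
    idx += 1
    mesh.n_pts = idx
    P0 = np.asarray(pt_positions)

    # ---- degrees of freedom and the map P = A u + b ----------------------
    dof_keys: list = []
    dof_of: dict = {}
    for i in range(N):
        if present[i] and not m.is_fixed[i]:
            dof_of[("NA", i)] = len(dof_keys)
            dof_keys.append(("NA", i))
            dof_of[("NB", i)] = len(dof_keys)
            dof_keys.append(("NB", i))
    for layer, t in sorted(relaxed):
        dof_of[("RV", layer, t)] = len(dof_keys)
        dof_keys.append(("RV", layer, t))
    for r in records:
        dof_of[("IV", r.quad)] = len(dof_keys)
        dof_keys.append(("IV", r.quad))
    mesh.dof_keys = dof_keys
    U = len(dof_keys)

    rows, cols, vals = [], [], []
    b = np.zeros(3 * mesh.n_pts)

    def _add_point(p, contribs, const=None):
        """contribs: list of (dof_slot or None, weight, fallback position)."""
        for slot, w, pos in contribs:
            if slot is None:
                b[3 * p : 3 * p + 3] += w * pos
            else:
                for c in range(3):
                    rows.append(3 * p + c)
                    cols.append(3 * slot + c)
                    vals.append(w)

    for i in range(N):
        if not present[i]:
            b[3 * i : 3 * i + 3] = m.apical[i]
            b[3 * (N + i) : 3 * (N + i) + 3] = m.basal[i]
            continue
        sa = dof_of.get(("NA", i))
        _add_point(i, [(sa, 1.0, m.apical[i])])
        sb = dof_of.get(("NB", i))
        _add_point(N + i, [(sb, 1.0, m.basal[i])])

    for (layer, t), p in mesh.pt_vert.items():
        if (layer, t) in relaxed:
            _add_point(p, [(dof_of[("RV", layer, t)], 1.0, None)])
        else:
            pref = "NA" if layer == LAYER_APICAL else "NB"
            arr = m.apical if layer == LAYER_APICAL else m.basal
            _add_point(p, [(dof_of.get((pref, v)), 1.0 / 3.0, arr[v]) for v in t])
    for q, p in mesh.pt_inter.items():
        _add_point(p, [(dof_of[("IV", q)], 1.0, None)])
    for i, p in mesh.pt_mid.items():
        _add_point(
            p,
            [
                (dof_of.get(("NA", i)), 0.5, m.apical[i]),
                (dof_of.get(("NB", i)), 0.5, m.basal[i]),
            ],
        )

    mesh.A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(3 * mesh.n_pts, 3 * U)
    )
    mesh.b = b

    # ---- segments --------------------------------------------------------
    seg_keys: list = []
    seg_p: list = []

    def _mixed(e) -> bool:
        return {cs[e[0]], cs[e[1]]} >= {STATE_ALIVE, STATE_ABLATED}

    def _tri_mixed(t) -> bool:
        sts = {int(cs[v]) for v in t}
        return STATE_ALIVE in sts and STATE_ABLATED in sts

    # nodal network: in-layer edges, verticals, diagonals
    for e in sorted(ea):
        i, j = e
        if m.is_ring[i] and m.is_ring[j]:
            continue
        seg_keys.append(("NA", i, j))
        seg_p.append((i, j))
    for e in sorted(eb):
        i, j = e
        if m.is_ring[i] and m.is_ring[j]:
            continue
        seg_keys.append(("NB", i, j))
        seg_p.append((N + i, N + j))
    for i in sorted(cell_ids):
        seg_keys.append(("NV", int(i)))
        seg_p.append((i, N + i))
    for e in sorted(ea | eb):
        i, j = e
        if m.is_ring[i] and m.is_ring[j]:
            continue
        seg_keys.append(("ND", i, j))
        seg_p.append((i, N + j))  # apical of the lower id to basal of the higher

    # vertex network: in-layer dual segments
    for e in sorted(ea):
        ts = map_a[e]
        if len(ts) == 2:
            seg_keys.append(("VA", e[0], e[1]))
            seg_p.append(
                (mesh.pt_vert[(LAYER_APICAL, ts[0])], mesh.pt_vert[(LAYER_APICAL, ts[1])])
            )
    for e in sorted(eb):
        ts = map_b[e]
        if len(ts) == 2:
            seg_keys.append(("VB", e[0], e[1]))
            seg_p.append(
                (mesh.pt_vert[(LAYER_BASAL, ts[0])], mesh.pt_vert[(LAYER_BASAL, ts[1])])
            )
    # lateral vertical vertex segments: triangles present in both layers
    for t in tri_a:
        if t in set_b:
            seg_keys.append(("VV", t))
            seg_p.append((mesh.pt_vert[(LAYER_APICAL, t)], mesh.pt_vert[(LAYER_BASAL, t)]))
    # intermediate-vertex spokes
    for r in records:
        g = mesh.pt_inter[r.quad]
        for t in r.apical_tris:
            seg_keys.append(("WS", r.quad, (LAYER_APICAL, t)))
            seg_p.append((mesh.pt_vert[(LAYER_APICAL, t)], g))
        for t in r.basal_tris:
            seg_keys.append(("WS", r.quad, (LAYER_BASAL, t)))
            seg_p.append((mesh.pt_vert[(LAYER_BASAL, t)], g))

    # ---- cells: loops, lateral faces, diagonals --------------------------
    cells = sorted(int(i) for i in cell_ids)
    mesh.cells = np.asarray(cells, dtype=np.int64)
    mesh.cell_V0 = m.V0[mesh.cells].astype(float)
    mesh.cell_penalty = cs[mesh.cells] == STATE_ALIVE

    faces: list = []
    diag_keys: dict = {}  # ('VD', i, j) -> (pt_a, pt_b), to dedupe across cells

    for ci, i in enumerate(cells):
        order_a, nbr_a = _fan_around(i, [t for t in tri_a if i in t], xy_a)
        order_b, nbr_b = _fan_around(i, [t for t in tri_b if i in t], xy_b)
        loop_a = [mesh.pt_vert[(LAYER_APICAL, tri_key(t))] for t in order_a]
        loop_b = [mesh.pt_vert[(LAYER_BASAL, tri_key(t))] for t in order_b]
        mesh.cell_apical_loop.append(loop_a)
        mesh.cell_basal_loop.append(loop_b)
        na_i = int(i)
        nb_i = N + int(i)
        mid = mesh.pt_mid[int(i)]
        ma = len(order_a)
        mb = len(order_b)
        # caps
        for t in range(ma):
            faces.append((ci, (na_i, loop_a[t], loop_a[(t + 1) % ma])))
        for t in range(mb):
            faces.append((ci, (nb_i, loop_b[(t + 1) % mb], loop_b[t])))
        # lateral
        b_index = {j: u for u, j in enumerate(nbr_b)}
        for t, j in enumerate(nbr_a):
            e = (i, j) if i < j else (j, i)
            va_lo = loop_a[t]
            va_hi = loop_a[(t + 1) % ma]
            if e in eb:  # matched lateral quad
                if j not in b_index:
                    raise GeometryError(
                        f"cell {i}: neighbour {j} present apically but missing "
                        "from basal loop despite matched edge"
                    )
                u = b_index[j]
                wb_lo = loop_b[u]
                wb_hi = loop_b[(u + 1) % mb]
                # diagonal choice: apical corner adjacent to the lower-id
                # flank neighbour connects to the opposite basal corner
                flank_lo = nbr_a[(t - 1) % ma]
                flank_hi = nbr_a[(t + 1) % ma]
                if flank_lo <= flank_hi:
                    diag = (va_lo, wb_hi)
                    faces.append((ci, (va_lo, wb_lo, wb_hi)))
                    faces.append((ci, (va_lo, wb_hi, va_hi)))
                else:
                    diag = (va_hi, wb_lo)
                    faces.append((ci, (va_hi, va_lo, wb_lo)))
                    faces.append((ci, (va_hi, wb_lo, wb_hi)))
                dk = ("VD", e[0], e[1])
                if dk not in diag_keys:
                    diag_keys[dk] = diag
            else:  # apical-only edge: stitch through the intermediate vertex
                r = rec_by_aedge.get(e)
                if r is None:
                    raise GeometryError(f"apical edge {e} is unmatched and unpaired")
                g = mesh.pt_inter[r.quad]
                bt = next(t2 for t2 in r.basal_tris if i in t2)
                vb = mesh.pt_vert[(LAYER_BASAL, bt)]
                faces.append((ci, (va_lo, g, va_hi)))
                faces.append((ci, (va_lo, vb, g)))
                faces.append((ci, (vb, va_hi, g)))
        for u, j in enumerate(nbr_b):
            e = (i, j) if i < j else (j, i)
            if e in ea:
                continue  # matched: already emitted from the apical pass
            r = rec_by_bedge.get(e)
            if r is None:
                raise GeometryError(f"basal edge {e} is unmatched and unpaired")
            g = mesh.pt_inter[r.quad]
            at = next(t2 for t2 in r.apical_tris if i in t2)
            va = mesh.pt_vert[(LAYER_APICAL, at)]
            wb_lo = loop_b[u]
            wb_hi = loop_b[(u + 1) % mb]
            faces.append((ci, (wb_hi, g, wb_lo)))
            faces.append((ci, (va, wb_lo, g)))
            faces.append((ci, (wb_hi, va, g)))

    for dk in sorted(diag_keys):
        seg_keys.append(dk)
        seg_p.append(diag_keys[dk])

    mesh.faces = faces
    mesh.tets = np.array(
        [
            (mesh.pt_mid[cells[ci]], f[0], f[1], f[2])
            for ci, f in faces
        ],
        dtype=np.int64,
    )
    mesh.tet_cell = np.array([ci for ci, _ in faces], dtype=np.int64)

    # padded per-cell point lists for the volume-penalty rank-1 blocks
    ncell = len(cells)
    cell_pt_lists: list[list[int]] = [[] for _ in range(ncell)]
    seen: list[dict] = [dict() for _ in range(ncell)]
    tet_slot = np.zeros_like(mesh.tets)
    for ti, (ci, _) in enumerate(faces):
        for corner in range(4):
            p = int(mesh.tets[ti, corner])
            slot = seen[ci].get(p)
            if slot is None:
                slot = len(cell_pt_lists[ci])
                seen[ci][p] = slot
                cell_pt_lists[ci].append(p)
            tet_slot[ti, corner] = slot
    W = max((len(lst) for lst in cell_pt_lists), default=1)
    cell_pts = np.full((ncell, W), dummy, dtype=np.int64)
    for ci, lst in enumerate(cell_pt_lists):
        cell_pts[ci, : len(lst)] = lst
    mesh.cell_pts = cell_pts
    mesh.tet_slot = tet_slot

    # ---- segment attributes, rest-length state ---------------------------
    mesh.seg_keys = seg_keys
    mesh.seg_p = np.asarray(seg_p, dtype=np.int64)
    nseg = len(seg_keys)
    mesh.seg_is_vertex = np.array(
        [k[0] in ("VA", "VB", "VV", "VD", "WS") for k in seg_keys], dtype=bool
    )
    # lateral vertex segments carry no intrinsic contractile set point: they
    # remodel as Maxwell elements (ε_c = 0), the junctional (in-plane)
    # cortex carries ε_c
    mesh.seg_lateral = np.array(
        [k[0] in ("VV", "VD", "WS") for k in seg_keys], dtype=bool
    )
    scale = np.ones(nseg)
    sched = np.zeros(nseg, dtype=np.int8)
    for s, k in enumerate(seg_keys):
        parents = _segment_parent_states(k, cs)
        if k[0] in ("NA", "NB", "NV", "ND"):
            # nodal springs model the cell body: an ablated cell's centre
            # loses its anchoring, so any ablated parent degrades the spring
            degraded = STATE_ABLATED in parents
        else:
            # the vertex network is junctional cortex: the interface cortex
            # belongs to the surviving cell too and keeps full stiffness
            degraded = bool(parents) and all(p == STATE_ABLATED for p in parents)
        if degraded:
            scale[s] = m.ablated_scale
        kind = k[0]
        if kind == "VA" and _mixed((k[1], k[2])):
            sched[s] = SCHED_APICAL
        elif kind == "VD" and _mixed((k[1], k[2])):
            sched[s] = SCHED_LATERAL
        elif kind == "VV" and _tri_mixed(k[1]):
            sched[s] = SCHED_LATERAL
        elif kind == "WS" and _tri_mixed(k[1]):
            sched[s] = SCHED_LATERAL
    mesh.seg_scale = scale
    mesh.seg_sched = sched

    lengths = np.linalg.norm(
        P0[mesh.seg_p[:, 1]] - P0[mesh.seg_p[:, 0]], axis=1
    ) if nseg else np.zeros(0)
    L = np.empty(nseg)
    L0 = np.empty(nseg)
    for s, k in enumerate(seg_keys):
        st = m.seg_state.get(k)
        if st is None:
            # stress-free birth: a freshly created segment carries no force
            m.seg_state[k] = [float(lengths[s]), float(lengths[s])]
            st = m.seg_state[k]
        L[s], L0[s] = st
    mesh.L = L
    mesh.L0 = L0
    # drop stale registry entries
    live = set(seg_keys)
    for k in [k for k in m.seg_state if k not in live]:
        del m.seg_state[k]

    # ---- wound perimeter -------------------------------------------------
    perim = [
        s
        for s, k in enumerate(seg_keys)
        if k[0] == "VA" and _mixed((k[1], k[2]))
    ]
    mesh.perim_seg_idx = np.asarray(perim, dtype=np.int64)
    if perim:
        pts = np.unique(mesh.seg_p[perim].ravel())
        mesh.perim_pt_ids = pts
        pset = set(int(p) for p in pts)
        edge_cells = []
        for ci, i in enumerate(cells):
            if cs[i] == STATE_ALIVE and any(
                p in pset for p in mesh.cell_apical_loop[ci]
            ):
                edge_cells.append(i)
        mesh.edge_cell_ids = np.asarray(edge_cells, dtype=np.int64)
    return mesh


# ---------------------------------------------------------------------------
# public geometry operations


def interpolate_vertices(m: Monolayer) -> dict:
    """Positions of all constrained vertices: barycentres of their parent
    triangles in their own layer (interpolation weights 1/3 each).

    Relaxed (wound-edge) and intermediate vertices carry their own degrees of
    freedom and are not touched.  Returns ``{(layer, tri): position}``.
    """
    mesh = m.mesh()
    out = {}
    for key in mesh.pt_vert:
        if key in mesh.relaxed:
            continue
        layer, t = key
        arr = m.apical if layer == LAYER_APICAL else m.basal
        out[key] = arr[list(t)].mean(axis=0)
    return out


def cell_volumes(mesh: Mesh, P: np.ndarray) -> np.ndarray:
    """Signed volumes of all cells from the midpoint-fan tetrahedra."""
    q = P[mesh.tets]
    e1 = q[:, 1] - q[:, 0]
    e2 = q[:, 2] - q[:, 0]
    e3 = q[:, 3] - q[:, 0]
    vt = np.einsum("ij,ij->i", e1, np.cross(e2, e3)) / 6.0
    V = np.zeros(len(mesh.cells))
    np.add.at(V, mesh.tet_cell, vt)
    return V


def cell_volume(m: Monolayer, cell_id: int) -> float:
    """Volume of one cell (model units³), signed-tetrahedron decomposition.

    Raises :class:`GeometryError` for inverted cells (volume <= 0 with a
    non-degenerate height); collapsed (zero-height) cells return 0.
    """
    mesh = m.mesh()
    where = np.flatnonzero(mesh.cells == cell_id)
    if len(where) == 0:
        raise KeyError(f"node {cell_id} carries no live/ablated cell")
    V = float(cell_volumes(mesh, mesh.positions())[where[0]])
    if V < -1e-12:
        raise GeometryError(f"cell {cell_id} is inverted (V={V:.3g})")
    return max(V, 0.0)


def polygon_area_xy(P: np.ndarray, loop) -> float:
    """Shoelace area of a vertex loop projected along the apico-basal axis."""
    pts = P[list(loop)][:, :2]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def mesh_audit(m: Monolayer) -> None:
    """Brute-force structural audit; raises GeometryError on any violation.

    Checks: every constrained vertex sits exactly at its parent triangle's
    barycentre; every lateral face is either shared by exactly two cells with
    opposite orientation or lies on the wound/patch boundary; cell volumes
    are positive for non-degenerate cells.
    """
    mesh = m.mesh()
    P = mesh.positions()
    for (layer, t), p in mesh.pt_vert.items():
        if (layer, t) in mesh.relaxed:
            continue
        arr = m.apical if layer == LAYER_APICAL else m.basal
        if not np.allclose(P[p], arr[list(t)].mean(axis=0), rtol=0, atol=1e-12):
            raise GeometryError(f"constrained vertex {(layer, t)} is not barycentric")
    # face sharing: lateral faces only (caps are exterior by construction)
    node_pts = set(range(2 * m.n_nodes))
    counts: dict = {}
    for ci, f in mesh.faces:
        if any(p in node_pts for p in f):
            continue  # cap face (contains a node point)
        key = tuple(sorted(f))
        counts.setdefault(key, []).append((ci, f))
    cs = m.cell_state
    for key, inc in counts.items():
        if len(inc) == 1:
            ci, f = inc[0]
            continue  # patch boundary or wound-facing
        if len(inc) != 2:
            raise GeometryError(f"face {key} shared by {len(inc)} cells")
        (_, f1), (_, f2) = inc
        # opposite orientation: f2 must be an odd permutation of f1
        r1 = list(f1)
        k = r1.index(f2[0])
        same = all(r1[(k + s) % 3] == f2[s] for s in range(3))
        if same:
            raise GeometryError(f"face {key} has identical orientation in both cells")
    V = cell_volumes(mesh, P)
    bad = np.flatnonzero(V <= 0)
    for ci in bad:
        raise GeometryError(f"cell {mesh.cells[ci]} has non-positive volume {V[ci]:.3g}")


# ---------------------------------------------------------------------------
# monolayer construction


def _boundary_ring(xy: np.ndarray, spacing: float) -> np.ndarray:
    """Mirror near-edge centres across the patch bounding box to create a
    ring of boundary nodes that are not the centre of any cell."""
    lo = xy.min(axis=0) - 0.35 * spacing
    hi = xy.max(axis=0) + 0.35 * spacing
    ring = []
    margin = 1.05 * spacing
    for p in xy:
        for axis in (0, 1):
            if p[axis] - lo[axis] < margin:
                q = p.copy()
                q[axis] = 2 * lo[axis] - p[axis]
                ring.append(q)
            if hi[axis] - p[axis] < margin:
                q = p.copy()
                q[axis] = 2 * hi[axis] - p[axis]
                ring.append(q)
        # corner (double) reflections
        for ax, ay in ((0, 1),):
            cx = None
            if p[0] - lo[0] < margin:
                cx = 2 * lo[0] - p[0]
            elif hi[0] - p[0] < margin:
                cx = 2 * hi[0] - p[0]
            cy = None
            if p[1] - lo[1] < margin:
                cy = 2 * lo[1] - p[1]
            elif hi[1] - p[1] < margin:
                cy = 2 * hi[1] - p[1]
            if cx is not None and cy is not None:
                ring.append(np.array([cx, cy]))
    if not ring:
        return np.zeros((0, 2))
    ring = np.asarray(ring)
    # dedupe clustered mirrors
    keep: list[np.ndarray] = []
    for q in ring:
        if all(np.linalg.norm(q - r) > 0.45 * spacing for r in keep):
            keep.append(q)
    return np.asarray(keep)


def build_monolayer(
    centers: pd.DataFrame,
    height_um: float = 35.0,
    length_unit_um: float = 60.0,
) -> Monolayer:
    """Build the initial two-layer monolayer from a cell-centre table (μm).

    Apical and basal layers start with identical centres and triangulations,
    separated by ``height_um`` along z (apical on top).  A mirrored ring of
    boundary nodes (not the centre of any cell) closes the polygons of the
    outermost cells; ring nodes and the outermost cells' centres are fixed.
    All rest lengths are initialised to current lengths and reference volumes
    to current volumes, so the initial state is exactly stress-free.
    """
    xy_um = centers[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy_um) < 7:
        raise GeometryError("need at least 7 cell centres")
    centred = xy_um - xy_um.mean(axis=0)
    if np.linalg.svd(centred, compute_uv=False)[-1] < 1e-9 * np.abs(centred).max():
        raise GeometryError("cell centres are collinear; cannot triangulate")
    xy = xy_um / length_unit_um
    h = height_um / length_unit_um

    d2 = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    np.fill_diagonal(d2, np.inf)
    spacing = float(np.median(d2.min(axis=1)))

    ring = _boundary_ring(xy, spacing)
    all_xy = np.vstack([xy, ring])
    n_cells = len(xy)
    N = len(all_xy)

    try:
        tri = Delaunay(all_xy)
    except (QhullError, ValueError, np.linalg.LinAlgError) as err:
        raise GeometryError(f"degenerate centre configuration: {err}") from err
    tris = sorted(tri_key(t) for t in tri.simplices)

    apical = np.c_[all_xy, np.full(N, h)]
    basal = np.c_[all_xy, np.zeros(N)]
    is_ring = np.zeros(N, dtype=bool)
    is_ring[n_cells:] = True
    cell_state = np.full(N, STATE_NONE, dtype=np.int8)
    cell_state[:n_cells] = STATE_ALIVE

    # outermost cells (adjacent to a ring node) are fixed, like the ring
    is_fixed = is_ring.copy()
    for t in tris:
        if any(is_ring[v] for v in t):
            for v in t:
                is_fixed[v] = True

    m = Monolayer(
        apical=apical,
        basal=basal,
        is_ring=is_ring,
        is_fixed=is_fixed,
        cell_state=cell_state,
        V0=np.full(N, np.nan),
        tri_a=list(tris),
        tri_b=list(tris),
        height=h,
        length_unit=length_unit_um,
    )
    mesh = m.mesh()
    V = cell_volumes(mesh, mesh.positions())
    if np.any(V <= 0):
        raise GeometryError("non-positive initial cell volume")
    m.V0[mesh.cells] = V
    areas = [
        polygon_area_xy(mesh.positions(), loop) for loop in mesh.cell_apical_loop
    ]
    m.init_mean_cell_area = float(np.mean(areas))
    P = mesh.positions()
    va = [s2 for s2, k in enumerate(mesh.seg_keys) if k[0] == "VA"]
    lv = np.linalg.norm(P[mesh.seg_p[va, 1]] - P[mesh.seg_p[va, 0]], axis=1)
    m.init_mean_junction_len = float(lv.mean())
    m.invalidate_mesh()  # rebuild with the reference volumes in place
    return m
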