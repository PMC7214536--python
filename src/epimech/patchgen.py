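"""Synthetic cell-centre patches on a jittered hexagonal lattice.

Experimental centre-of-mass tables are not distributed with the study this
model targets, so downstream stages are exercised on synthetic patches that
emulate their statistical structure: roughly uniform centres on a bounded
square region, hexagonal neighbour topology, and mild positional noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

__all__ = [
    "PatchSpec",
    "PatchSizingError",
    "generate_hex_patch",
    "select_ablation_region",
    "write_centers_csv",
    "read_centers_csv",
]

#: Default lattice spacing (centre-to-centre distance), in μm.
DEFAULT_SPACING_UM = 9.0


class PatchSizingError(ValueError):
    """Requested cell count is not achievable for the given patch geometry."""


@dataclass(frozen=True)
class PatchSpec:
    """Specification of a synthetic monolayer patch.

    Parameters
    ----------
    n_cells:
        Number of cell centres; at least 7 so that one interior cell exists.
    patch_side:
        Side of the square the lattice is clipped to, in μm.  ``None`` derives
        it from ``n_cells`` and ``spacing`` so that the hexagonal packing
        fills the square.
    noise_amplitude:
        Per-centre jitter radius as a fraction of the lattice spacing, in
        ``[0, 0.5)``.  Below 0.5 no two centres can collide.
    height:
        Initial monolayer height (apico-basal extent), in μm.
    seed:
        Seed of the patch-owned random generator.
    spacing:
        Hexagonal lattice constant in μm (free knob; the source study reports
        no density statistics).
    """

    n_cells: int
    patch_side: float | None = None
    noise_amplitude: float = 0.0
    height: float = 35.0
    seed: int = 0
    spacing: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if self.n_cells < 7:
            raise ValueError("n_cells must be >= 7 (at least one interior cell)")
        if not (0.0 <= self.noise_amplitude < 0.5):
            raise ValueError("noise_amplitude must lie in [0, 0.5)")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.patch_side is not None and self.patch_side <= 0:
            raise ValueError("patch_side must be positive")

    @property
    def side(self) -> float:
        """Resolved patch side (μm)."""
        if self.patch_side is not None:
            return self.patch_side
        # area per hexagonally packed centre is (sqrt(3)/2) s^2
        return float(np.sqrt(self.n_cells * (np.sqrt(3.0) / 2.0)) * self.spacing)


def _hex_lattice(side: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice covering (with margin) the square [0, side]^2."""
    dy = spacing * np.sqrt(3.0) / 2.0
    n_col = int(np.ceil(side / spacing)) + 3
    n_row = int(np.ceil(side / dy)) + 3
    pts = []
    for r in range(-1, n_row):
        y = r * dy
        x0 = 0.5 * spacing if r % 2 else 0.0
        for c in range(-1, n_col):
            pts.append((x0 + c * spacing, y))
    return np.asarray(pts, dtype=float)


def generate_hex_patch(spec: PatchSpec) -> pd.DataFrame:
    """Generate jittered hexagonal cell centres clipped to a square patch.

    Returns a table with columns ``cell_id``, ``x_um``, ``y_um``.  The result
    is deterministic for a fixed ``spec`` (single seeded generator, no global
    state).  Centres are ranked by distance to the patch centre so that, when
    the clipped lattice holds more than ``n_cells`` points, the surplus is
    shed from the patch margin and the patch stays square-ish.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    lattice = _hex_lattice(side, spec.spacing)

    # 7-centre rosette special-cased: a perfect hexagon + centre, independent
    # of the square clip (the smallest patch with one interior cell).
    if spec.n_cells == 7:
        c = side / 2.0
        ang = np.pi / 6.0 + np.arange(6) * np.pi / 3.0
        pts = np.concatenate(
            [[[c, c]], np.c_[c + spec.spacing * np.cos(ang), c + spec.spacing * np.sin(ang)]]
        )
    else:
        margin = 1e-9 * side
        inside = (
            (lattice[:, 0] >= -margin)
            & (lattice[:, 0] <= side + margin)
            & (lattice[:, 1] >= -margin)
            & (lattice[:, 1] <= side + margin)
        )
        pts = lattice[inside]
        if len(pts) < spec.n_cells:
            raise PatchSizingError(
                f"only {len(pts)} lattice sites fit in a {side:.3g} μm square at "
                f"spacing {spec.spacing:.3g} μm; {spec.n_cells} requested"
            )
        centre = pts.mean(axis=0)
        order = np.argsort(np.linalg.norm(pts - centre, axis=1), kind="stable")
        pts = pts[order[: spec.n_cells]]

    if spec.noise_amplitude > 0.0:
        r = spec.noise_amplitude * spec.spacing * np.sqrt(rng.uniform(size=len(pts)))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=len(pts))
        jitter = np.c_[r * np.cos(phi), r * np.sin(phi)]
        pts = _relax_slivers(pts, jitter)

    return pd.DataFrame(
        {"cell_id": np.arange(len(pts)), "x_um": pts[:, 0], "y_um": pts[:, 1]}
    )


def _relax_slivers(
    lattice: np.ndarray, jitter: np.ndarray, max_aspect: float = 4.5
) -> np.ndarray:
    """Deterministically shrink the jitter of points that produce sliver
    triangles (aspect ratio > ``max_aspect``), so the triangulated patch
    keeps the quality of real epithelial centre clouds."""
    pts = lattice + jitter
    for _ in range(50):
        tri = Delaunay(pts)
        bad = set()
        for t in tri.simplices:
            p = pts[t]
            e = np.array(
                [
                    np.linalg.norm(p[1] - p[0]),
                    np.linalg.norm(p[2] - p[1]),
                    np.linalg.norm(p[0] - p[2]),
                ]
            )
            if e.min() <= 0 or e.max() / e.min() > max_aspect:
                bad.update(int(v) for v in t)
        if not bad:
            break
        # Lloyd-style smoothing of the offending points only: blend toward
        # the centroid of their Delaunay neighbours
        nbrs: dict[int, set[int]] = {v: set() for v in bad}
        for t in tri.simplices:
            for v in t:
                if int(v) in nbrs:
                    nbrs[int(v)].update(int(w) for w in t if w != v)
        new = pts.copy()
        for v, ns in nbrs.items():
            new[v] = 0.5 * pts[v] + 0.5 * pts[sorted(ns)].mean(axis=0)
        pts = new
    return pts


def delaunay_adjacency(centers: pd.DataFrame) -> dict[int, set[int]]:
    """Cell adjacency graph from the Delaunay triangulation of the centres."""
    xy = centers[["x_um", "y_um"]].to_numpy()
    tri = Delaunay(xy)
    adj: dict[int, set[int]] = {int(i): set() for i in centers["cell_id"]}
    ids = centers["cell_id"].to_numpy()
    for a, b, c in tri.simplices:
        for u, v in ((a, b), (b, c), (a, c)):
            adj[int(ids[u])].add(int(ids[v]))
            adj[int(ids[v])].add(int(ids[u]))
    return adj


def boundary_cell_ids(centers: pd.DataFrame) -> set[int]:
    """Cells on the convex hull of the centre cloud (their centres are fixed
    during simulations, so they may not be ablated)."""
    xy = centers[["x_um", "y_um"]].to_numpy()
    ids = centers["cell_id"].to_numpy()
    hull = Delaunay(xy).convex_hull
    return {int(ids[i]) for i in np.unique(hull)}


def select_ablation_region(centers: pd.DataFrame, n_ablate: int) -> set[int]:
    """Select the ``n_ablate`` cells nearest the patch centroid.

    The returned set is edge-connected in the Delaunay adjacency graph: the
    region is grown from the most central cell, at each step adding the
    adjacent cell closest to the centroid.  Raises ``ValueError`` if the
    region would touch the patch boundary (boundary cell centres are fixed).
    """
    xy = centers[["x_um", "y_um"]].to_numpy()
    ids = centers["cell_id"].to_numpy()
    if not 1 <= n_ablate < len(ids):
        raise ValueError("1 <= n_ablate < number of cells required")
    centroid = xy.mean(axis=0)
    dist = {int(i): float(d) for i, d in zip(ids, np.linalg.norm(xy - centroid, axis=1))}
    adj = delaunay_adjacency(centers)
    boundary = boundary_cell_ids(centers)

    start = min(dist, key=lambda i: (dist[i], i))
    region = {start}
    while len(region) < n_ablate:
        frontier = {j for i in region for j in adj[i]} - region
        if not frontier:
            raise ValueError("cannot grow a connected ablation region")
        region.add(min(frontier, key=lambda i: (dist[i], i)))
    touching = region & boundary
    if touching:
        raise ValueError(
            f"ablation region touches the patch boundary (cells {sorted(touching)}); "
            "boundary cells are fixed and cannot be ablated"
        )
    return region


def write_centers_csv(centers: pd.DataFrame, path) -> None:
    centers.to_csv(path, index=False, columns=["cell_id", "x_um", "y_um"])


def read_centers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"cell_id", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"centers CSV missing columns: {sorted(missing)}")
    return df
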