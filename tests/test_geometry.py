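"""Prism-cell geometry: barycentric vertices, volumes, aspect ratio, and the
structural audit of the two-layer mesh."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from epimech.geometry import (
    GeometryError,
    LAYER_APICAL,
    Monolayer,
    build_monolayer,
    cell_volume,
    cell_volumes,
    interpolate_vertices,
    mesh_audit,
    polygon_area_xy,
    triangle_aspect_ratio,
)


class TestAspectRatio:
    def test_equilateral_is_one(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        assert triangle_aspect_ratio(*p) == pytest.approx(1.0)

    def test_right_isoceles(self):
        r = triangle_aspect_ratio([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert r == pytest.approx(np.sqrt(2.0))

    def test_sliver(self):
        # edges 1, 1, ~1.999: ratio approaches the long/short quotient
        c = 1.9995
        x = c / 2
        y = np.sqrt(1 - x**2)
        r = triangle_aspect_ratio([0, 0, 0], [c, 0, 0], [x, y, 0])
        assert r == pytest.approx(c, rel=1e-9)

    def test_degenerate_is_infinite(self):
        assert triangle_aspect_ratio([0, 0, 0], [1, 0, 0], [0, 0, 0]) == np.inf


class TestInterpolation:
    def test_barycenter_example(self, rosette):
        verts = interpolate_vertices(rosette)
        for (layer, t), pos in verts.items():
            arr = rosette.apical if layer == LAYER_APICAL else rosette.basal
            np.testing.assert_allclose(pos, arr[list(t)].mean(axis=0), atol=1e-14)

    def test_translation_equivariance(self, patch20):
        before = interpolate_vertices(patch20)
        shift = np.array([1.7, -0.3, 0.4])
        patch20.apical += shift
        patch20.basal += shift
        patch20.invalidate_mesh()
        after = interpolate_vertices(patch20)
        for key, pos in before.items():
            np.testing.assert_allclose(after[key], pos + shift, atol=1e-12)


class TestBuild:
    def test_rosette_central_cell_is_hexagonal_prism(self, rosette):
        mesh = rosette.mesh()
        # the central cell (node 0) has 6 apical and 6 basal vertices
        ci = list(mesh.cells).index(0)
        assert len(mesh.cell_apical_loop[ci]) == 6
        assert len(mesh.cell_basal_loop[ci]) == 6

    def test_audit_passes_on_fresh_builds(self, rosette, patch20):
        mesh_audit(rosette)
        mesh_audit(patch20)

    def test_collinear_centers_rejected(self):
        df = pd.DataFrame(
            {"cell_id": range(8), "x_um": np.arange(8.0), "y_um": np.zeros(8)}
        )
        with pytest.raises(GeometryError):
            build_monolayer(df)

    def test_interior_lateral_faces_shared_twice(self, patch20):
        """Exhaustive face-matching: every interior lateral face appears in
        exactly two cells (with opposite orientation)."""
        mesh = patch20.mesh()
        node_pts = set(range(2 * patch20.n_nodes))
        counts = {}
        for ci, f in mesh.faces:
            if any(p in node_pts for p in f):
                continue
            counts.setdefault(tuple(sorted(f)), []).append(ci)
        n_shared = sum(1 for v in counts.values() if len(v) == 2)
        assert n_shared > 0
        assert all(len(v) in (1, 2) for v in counts.values())


class TestVolume:
    def test_unit_cube_prism(self):
        """A handcrafted unit-square prism of height 1 has volume 1."""
        m = _square_prism(side=1.0, height=1.0)
        mesh = m.mesh()
        V = cell_volumes(mesh, mesh.positions())
        assert V[0] == pytest.approx(1.0, rel=1e-12)

    def test_hexagonal_prism_matches_convex_hull(self, rosette):
        mesh = rosette.mesh()
        P = mesh.positions()
        ci = list(mesh.cells).index(0)
        V = cell_volumes(mesh, P)[ci]
        pts = P[
            mesh.cell_apical_loop[ci]
            + mesh.cell_basal_loop[ci]
            + [0, rosette.n_nodes + 0]
        ]
        assert V == pytest.approx(ConvexHull(pts).volume, rel=1e-9)
        # regular hexagonal prism: V = (3*sqrt(3)/2) a^2 h with a the side
        a = np.linalg.norm(P[mesh.cell_apical_loop[ci][0]][:2] - P[mesh.cell_apical_loop[ci][1]][:2])
        assert V == pytest.approx(1.5 * np.sqrt(3) * a**2 * rosette.height, rel=1e-9)

    def test_zero_height_cell_collapses_to_zero(self):
        m = _square_prism(side=1.0, height=1.0)
        m.basal[:, 2] = m.apical[:, 2]  # collapse
        m.invalidate_mesh()
        mesh = m.mesh()
        V = cell_volumes(mesh, mesh.positions())
        assert V[0] == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(GeometryError):
            mesh_audit(m)

    def test_slab_volume_of_zero_noise_lattice(self):
        """Total cell volume of an intact zero-noise patch matches the slab
        area x height within 1% (interior cells exactly)."""
        from epimech.patchgen import PatchSpec, generate_hex_patch

        df = generate_hex_patch(PatchSpec(n_cells=40, noise_amplitude=0.0, seed=0))
        m = build_monolayer(df, height_um=35.0, length_unit_um=40.0)
        mesh = m.mesh()
        P = mesh.positions()
        V = cell_volumes(mesh, P)
        interior = ~m.is_fixed[mesh.cells]
        assert interior.sum() >= 5
        spacing = 9.0 / 40.0
        hex_area = np.sqrt(3) / 2 * spacing**2
        expected = hex_area * m.height
        np.testing.assert_allclose(V[interior], expected, rtol=1e-9)

    def test_cell_volume_api(self, rosette):
        assert cell_volume(rosette, 0) > 0
        with pytest.raises(KeyError):
            cell_volume(rosette, 10_000)


def _square_prism(side: float, height: float) -> Monolayer:
    """Single-cell square prism assembled directly (bypasses Delaunay)."""
    # node 0 at the centre; ring nodes 1-4 mirrored so that the 4 triangles'
    # barycentres... a direct construction is simpler: use 4 ring nodes at
    # the corners scaled so the barycentre polygon is the unit square.
    # ring nodes on the axes at radius 1.5·side: the triangle barycentres
    # (c + r_i + r_{i+1})/3 then sit at c + (side/2)(±1, ±1)/... i.e. the
    # vertex loop is an axis-aligned-diagonal square of area side².
    c = np.array([0.0, 0.0])
    dirs = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
    r = c + 1.5 * side * dirs
    xy = np.vstack([c, r])
    apical = np.c_[xy, np.full(5, height)]
    basal = np.c_[xy, np.zeros(5)]
    tris = [(0, 1, 2), (0, 2, 3), (0, 3, 4), (0, 1, 4)]
    tris = [tuple(sorted(t)) for t in tris]
    m = Monolayer(
        apical=apical,
        basal=basal,
        is_ring=np.array([False, True, True, True, True]),
        is_fixed=np.array([False, True, True, True, True]),
        cell_state=np.array([1, 0, 0, 0, 0], dtype=np.int8),
        V0=np.full(5, np.nan),
        tri_a=sorted(tris),
        tri_b=sorted(tris),
        height=height,
        length_unit=1.0,
    )
    mesh = m.mesh()
    m.V0[mesh.cells] = cell_volumes(mesh, mesh.positions())
    m.init_mean_cell_area = polygon_area_xy(mesh.positions(), mesh.cell_apical_loop[0])
    m.invalidate_mesh()
    return m
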