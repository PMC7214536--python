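"""Remeshing: Delaunay recovery at tol_r = 0, the quad-flip oracle,
connectivity-change bookkeeping and intermediate-vertex stitching."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

import networkx as nx

from epimech.geometry import (
    LAYER_APICAL,
    LAYER_BASAL,
    GeometryError,
    build_monolayer,
    edges_of,
    find_mismatches,
    mesh_audit,
    tri_key,
)
from epimech.patchgen import PatchSpec, generate_hex_patch
from epimech.remesh import (
    RemeshSettings,
    apply_connectivity_change,
    propose_flips,
    reconcile_intermediate_vertices,
    remesh_step,
)


def _random_scrambled_triangulation(xy, rng, n_scramble=6):
    """A valid but non-Delaunay triangulation: start from Delaunay and apply
    random valid flips (ignoring the Delaunay criterion)."""
    from epimech.remesh import _ccw
    from epimech.geometry import edge_tri_map

    tris = sorted(tri_key(t) for t in Delaunay(xy).simplices)
    done = 0
    edges = sorted(edges_of(tris))
    rng.shuffle(edges)
    for e in edges:
        if done >= n_scramble:
            break
        emap = edge_tri_map(tris)
        pair = emap.get(tuple(e), emap.get(e))
        if pair is None or len(pair) != 2:
            continue
        i, j = e
        k = next(v for v in pair[0] if v not in e)
        l = next(v for v in pair[1] if v not in e)
        if _ccw(xy[k], xy[l], xy[i]) * _ccw(xy[k], xy[l], xy[j]) >= 0:
            continue
        if _ccw(xy[i], xy[j], xy[k]) * _ccw(xy[i], xy[j], xy[l]) >= 0:
            continue
        tris = sorted(
            [t for t in tris if t not in pair] + [tri_key((i, k, l)), tri_key((j, k, l))]
        )
        done += 1
    return tris


class TestProposeFlips:
    def test_delaunay_configuration_is_fixed_point(self):
        df = generate_hex_patch(PatchSpec(n_cells=40, noise_amplitude=0.25, seed=8))
        xy = df[["x_um", "y_um"]].to_numpy()
        tris = sorted(tri_key(t) for t in Delaunay(xy).simplices)
        out, flips = propose_flips(tris, xy, tol_r=0.1)
        assert flips == []
        assert out == tris

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tol_zero_recovers_exact_delaunay(self, seed):
        """Flipping a scrambled triangulation at tol_r = 0 reproduces the
        library Delaunay triangulation exactly (edge-set equality)."""
        rng = np.random.default_rng(seed)
        df = generate_hex_patch(
            PatchSpec(n_cells=40, noise_amplitude=0.3, seed=100 + seed)
        )
        xy = df[["x_um", "y_um"]].to_numpy()
        tris = _random_scrambled_triangulation(xy, rng)
        out, _ = propose_flips(tris, xy, tol_r=0.0, max_flips=500)
        ref = sorted(tri_key(t) for t in Delaunay(xy).simplices)
        assert edges_of(out) == edges_of(ref)

    def test_kite_quad_flip_oracle(self):
        """The long diagonal of a kite quad is non-Delaunay and flips once;
        aspect ratios before/after verified by brute-force edge lengths."""
        xy = np.array([[0.0, 0.0], [2.0, -1.0], [4.0, 0.0], [2.0, 1.0]])
        tris = [tri_key((0, 1, 2)), tri_key((0, 2, 3))]  # diagonal 0-2
        from epimech.remesh import _aspect

        r_old = max(_aspect(xy, (0, 1, 2)), _aspect(xy, (0, 2, 3)))
        out, flips = propose_flips(tris, xy, tol_r=0.0, max_flips=10)
        assert flips == [(0, 2)]
        assert set(out) == {tri_key((0, 1, 3)), tri_key((1, 2, 3))}
        r_new = max(_aspect(xy, (0, 1, 3)), _aspect(xy, (1, 2, 3)))
        assert r_old == pytest.approx(4.0 / np.sqrt(5.0))
        assert r_new == pytest.approx(np.sqrt(5.0) / 2.0)
        assert r_new < r_old

    def test_aspect_gate_defers_quality_degrading_flip(self):
        """A Delaunay-improving flip that worsens the worst aspect ratio is
        deferred at tol_r = 0 but accepted at a permissive tolerance."""
        xy = np.array(
            [
                [0.12455471, 0.28833076],
                [0.58612306, 0.5540905],
                [0.80971078, 0.56047595],
                [0.28842121, 0.41289634],
            ]
        )
        tris = [tri_key((0, 1, 2)), tri_key((0, 1, 3))]  # shared edge 0-1
        out0, flips0 = propose_flips(tris, xy, tol_r=0.0, max_flips=10)
        assert flips0 == []  # r would grow by ~9%
        out_hi, flips_hi = propose_flips(tris, xy, tol_r=0.1, max_flips=10)
        assert flips_hi == [(0, 1)]
        assert set(out_hi) == {tri_key((0, 2, 3)), tri_key((1, 2, 3))}


class TestConnectivityChange:
    def test_noop_change_is_identity(self, patch20):
        before = [tuple(t) for t in patch20.tri_a]
        apply_connectivity_change(patch20, LAYER_APICAL, list(before))
        assert patch20.tri_a == sorted(before)
        mesh_audit(patch20)

    def test_single_apical_flip_exchanges_neighbours(self, patch40):
        """An apical-only flip swaps the apical junction (a–b → c–d) while
        basal loops are untouched, creating one intermediate vertex."""
        m = patch40
        mesh = m.mesh()
        # find an interior edge between two live cells with live opposites
        from epimech.geometry import edge_tri_map

        emap = edge_tri_map(m.tri_a)
        target = None
        for e, pair in sorted(emap.items()):
            if len(pair) != 2:
                continue
            i, j = e
            k = next(v for v in pair[0] if v not in e)
            l = next(v for v in pair[1] if v not in e)
            if all(m.cell_state[v] == 1 and not m.is_fixed[v] for v in (i, j, k, l)):
                target = (e, pair, k, l)
                break
        assert target is not None
        (i, j), pair, k, l = target
        new = [t for t in m.tri_a if t not in pair] + [
            tri_key((i, k, l)),
            tri_key((j, k, l)),
        ]
        ea_before = edges_of(m.tri_a)
        apply_connectivity_change(m, LAYER_APICAL, new)
        ea = edges_of(m.tri_a)
        eb = edges_of(m.tri_b)
        assert (i, j) not in ea and (min(k, l), max(k, l)) in ea
        assert (i, j) in eb  # basal untouched
        recs = reconcile_intermediate_vertices(m)
        assert len(recs) == 1
        assert recs[0].apical_edge == (min(k, l), max(k, l))
        mesh_audit(m)
        # the mismatched cell has an intermediate vertex on its lateral strip
        mesh = m.mesh()
        assert len(mesh.pt_inter) == 1

    def test_flip_restore_roundtrip_is_topology_identity(self, patch40):
        """Flipping apically and then flipping back restores a mesh that is
        graph-isomorphic to the original cell-boundary graph, with no
        intermediate vertices left."""
        m = patch40
        original = _boundary_graph(m)
        before = list(m.tri_a)
        from epimech.geometry import edge_tri_map

        emap = edge_tri_map(m.tri_a)
        for e, pair in sorted(emap.items()):
            if len(pair) != 2:
                continue
            i, j = e
            k = next(v for v in pair[0] if v not in e)
            l = next(v for v in pair[1] if v not in e)
            if all(m.cell_state[v] == 1 and not m.is_fixed[v] for v in (i, j, k, l)):
                new = [t for t in m.tri_a if t not in pair] + [
                    tri_key((i, k, l)),
                    tri_key((j, k, l)),
                ]
                apply_connectivity_change(m, LAYER_APICAL, new)
                assert len(m.mesh().pt_inter) == 1
                apply_connectivity_change(m, LAYER_APICAL, before)
                break
        assert len(m.mesh().pt_inter) == 0
        assert nx.is_isomorphic(original, _boundary_graph(m))
        mesh_audit(m)

    def test_unpairable_change_rejected(self, patch20):
        # removing a triangle outright (not a flip) leaves an unpairable hole
        broken = list(patch20.tri_a)[:-1]
        with pytest.raises(GeometryError):
            apply_connectivity_change(patch20, LAYER_APICAL, broken)


class TestRemeshStep:
    def test_equilibrium_patch_has_no_flips(self, patch20):
        events = remesh_step(patch20, RemeshSettings(tol_r=0.1))
        assert events == []

    def test_forced_equal_layers_never_creates_intermediates(self, patch40):
        m = patch40
        rng = np.random.default_rng(0)
        m.apical[:, :2] += 0.004 * rng.standard_normal((m.n_nodes, 2))
        m.basal[:, :2] += 0.004 * rng.standard_normal((m.n_nodes, 2))
        m.invalidate_mesh()
        remesh_step(m, RemeshSettings(tol_r=0.0, force_equal_layers=True))
        assert m.tri_a == m.tri_b
        assert len(m.mesh().pt_inter) == 0

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            RemeshSettings(tol_r=-0.1)


def _boundary_graph(m) -> nx.Graph:
    """Cell-boundary graph: vertices + segment connectivity of the mesh."""
    mesh = m.mesh()
    g = nx.Graph()
    for s, key in enumerate(mesh.seg_keys):
        a, b = mesh.seg_p[s]
        g.add_edge(int(a), int(b))
    return g
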