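"""Energy, residual and tangent: reference-state zeros, brute-force
summation oracle, finite-difference audits, active tension law."""

import numpy as np
import pytest

from epimech.geometry import cell_volumes
from epimech.mechanics import (
    MaterialParams,
    active_tension,
    assemble,
    schedule_array,
)


@pytest.fixture()
def params():
    return MaterialParams()


class TestEnergy:
    def test_zero_at_reference_state(self, patch20, params):
        mesh = patch20.mesh()
        asm = assemble(mesh, mesh.gather_u(), params, need_hess=False)
        assert asm.energy == pytest.approx(0.0, abs=1e-24)
        assert asm.norm == pytest.approx(0.0, abs=1e-12)

    def test_single_stretched_segment_energy(self):
        # (k_V/2)(l-L)^2 = 0.5 for l=2, L=1, k_V=1
        p = MaterialParams(k_V=1.0, k_V0=0.0, k_N=0.0, lambda_vol=0.0)
        l, L = 2.0, 1.0
        assert 0.5 * p.k_V * (l - L) ** 2 == pytest.approx(0.5)

    def test_brute_force_summation_oracle(self, patch20, params):
        """W matches an independent per-segment/per-cell summation."""
        mesh = patch20.mesh()
        rng = np.random.default_rng(11)
        u = mesh.gather_u() + 0.01 * rng.standard_normal(len(mesh.gather_u()))
        asm = assemble(mesh, u, params, need_hess=False)
        P = mesh.positions(u)
        W = 0.0
        for s, key in enumerate(mesh.seg_keys):
            l = np.linalg.norm(P[mesh.seg_p[s, 1]] - P[mesh.seg_p[s, 0]])
            sc = mesh.seg_scale[s]
            if mesh.seg_is_vertex[s]:
                W += sc * 0.5 * params.k_V * (l - mesh.L[s]) ** 2
                W += sc * 0.5 * params.k_V0 * (l - mesh.L0[s]) ** 2 / mesh.L0[s]
            else:
                W += sc * 0.5 * params.k_N * (l - mesh.L[s]) ** 2
        V = cell_volumes(mesh, P)
        for ci in range(len(mesh.cells)):
            if mesh.cell_penalty[ci]:
                W += 0.5 * params.lambda_vol * ((V[ci] - mesh.cell_V0[ci]) / mesh.cell_V0[ci]) ** 2
        assert asm.energy == pytest.approx(W, rel=1e-12)

    def test_energy_terms_are_nonnegative(self, patch20, params):
        mesh = patch20.mesh()
        rng = np.random.default_rng(5)
        for _ in range(3):
            u = mesh.gather_u() + 0.02 * rng.standard_normal(len(mesh.gather_u()))
            assert assemble(mesh, u, params, need_hess=False).energy >= 0.0


class TestActiveTension:
    def test_zero_without_strain_or_contractility(self, params):
        assert active_tension(params, l=1.0, L0=1.0, ups_hat=0.0) == 0.0

    def test_contractility_contribution(self):
        p = MaterialParams(k_V0=0.05)
        assert active_tension(p, l=1.0, L0=1.0, ups_hat=2.3) == pytest.approx(0.115)

    def test_tension_matches_energy_derivative(self, patch20, params):
        """The scheduled-contractility force equals the central difference of
        the augmented energy along the segment length."""
        mesh = patch20.mesh()
        ups = np.full(len(mesh.seg_keys), 0.7)
        ups[~mesh.seg_is_vertex] = 0.0
        u0 = mesh.gather_u()
        rng = np.random.default_rng(2)
        u0 = u0 + 0.01 * rng.standard_normal(len(u0))
        asm = assemble(mesh, u0, params, ups=ups, need_hess=False)
        h = 1e-6
        for k in rng.choice(len(u0), 12, replace=False):
            up, um = u0.copy(), u0.copy()
            up[k] += h
            um[k] -= h
            fd = (
                assemble(mesh, up, params, ups=ups, need_hess=False).energy
                - assemble(mesh, um, params, ups=ups, need_hess=False).energy
            ) / (2 * h)
            assert fd == pytest.approx(asm.grad[k], rel=1e-4, abs=1e-8)


class TestResidualAndJacobian:
    def test_translation_invariance(self, patch20, params):
        """Rigid translation of a stress-free state leaves ‖g‖ = 0."""
        m = patch20
        m.apical += np.array([0.3, -0.2, 0.15])
        m.basal += np.array([0.3, -0.2, 0.15])
        m.invalidate_mesh()
        mesh = m.mesh()
        asm = assemble(mesh, mesh.gather_u(), params, need_hess=False)
        assert asm.norm == pytest.approx(0.0, abs=1e-12)

    def test_residual_is_energy_gradient(self, patch20, params):
        """Residual blocks match central finite differences of the energy
        at relative error < 1e-5 on a randomly perturbed patch."""
        mesh = patch20.mesh()
        rng = np.random.default_rng(0)
        u = mesh.gather_u() + 0.02 * rng.standard_normal(len(mesh.gather_u()))
        asm = assemble(mesh, u, params, need_hess=False)
        h = 1e-6
        g_fd = np.zeros_like(u)
        for k in range(len(u)):
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            g_fd[k] = (
                assemble(mesh, up, params, need_hess=False).energy
                - assemble(mesh, um, params, need_hess=False).energy
            ) / (2 * h)
        assert np.abs(g_fd - asm.grad).max() / np.abs(asm.grad).max() < 1e-5

    def test_jacobian_matches_residual_differences(self, patch20, params):
        mesh = patch20.mesh()
        rng = np.random.default_rng(1)
        u = mesh.gather_u() + 0.02 * rng.standard_normal(len(mesh.gather_u()))
        H = assemble(mesh, u, params).hess.toarray()
        assert np.abs(H - H.T).max() <= 1e-10 * np.abs(H).max()
        h = 1e-6
        for k in rng.choice(len(u), 15, replace=False):
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            col = (
                assemble(mesh, up, params, need_hess=False).grad
                - assemble(mesh, um, params, need_hess=False).grad
            ) / (2 * h)
            assert np.abs(col - H[:, k]).max() < 1e-4 * max(np.abs(H).max(), 1.0)

    def test_zero_stiffness_gives_zero_operator(self, patch20):
        p0 = MaterialParams(k_N=0.0, k_V=0.0, k_V0=0.0, lambda_vol=0.0)
        mesh = patch20.mesh()
        rng = np.random.default_rng(4)
        u = mesh.gather_u() + 0.05 * rng.standard_normal(len(mesh.gather_u()))
        asm = assemble(mesh, u, p0)
        assert asm.norm == 0.0
        assert asm.hess.nnz == 0 or np.abs(asm.hess.toarray()).max() == 0.0

    def test_implicit_rest_length_tangent(self, patch20, params):
        """With the affine rest-length substitution L = a + c·l, the tangent
        matches finite differences of the substituted residual."""
        from epimech.rheology import rest_affine_coefficients

        mesh = patch20.mesh()
        u0 = mesh.gather_u()
        P = mesh.positions(u0)
        l_n = np.linalg.norm(P[mesh.seg_p[:, 1]] - P[mesh.seg_p[:, 0]], axis=1)
        eps = np.where(mesh.seg_lateral, 0.0, params.eps_c)
        a, c = rest_affine_coefficients(l_n, mesh.L, 0.6, 0.5, params.gamma, eps)
        rng = np.random.default_rng(3)
        u = u0 + 0.01 * rng.standard_normal(len(u0))
        asm = assemble(mesh, u, params, rest_affine=(a, c))
        H = asm.hess.toarray()
        h = 1e-6
        for k in rng.choice(len(u), 10, replace=False):
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            col = (
                assemble(mesh, up, params, rest_affine=(a, c), need_hess=False).grad
                - assemble(mesh, um, params, rest_affine=(a, c), need_hess=False).grad
            ) / (2 * h)
            assert np.abs(col - H[:, k]).max() < 1e-4 * max(np.abs(H).max(), 1.0)


def test_schedule_array_routing(patch20):
    from epimech.patchgen import select_ablation_region
    # schedules act only on wound-edge segments, split apical vs lateral
    mesh = patch20.mesh()
    ups = schedule_array(mesh, 2.0, 0.5)
    assert np.all(ups == 0.0)  # intact patch: nothing scheduled


def test_volume_deviation_monotone_in_penalty_weight():
    """On an intact relaxing patch, the max per-cell |V−V0|/V0 after a fixed
    relaxation span is non-increasing in the volume-penalty weight."""
    from epimech.geometry import build_monolayer
    from epimech.metrics import volume_deviation_stats
    from epimech.patchgen import PatchSpec, generate_hex_patch
    from epimech.remesh import RemeshSettings
    from epimech.solver import SolverSettings, run_simulation
    from epimech.wound import WoundProtocol

    devs = []
    for lam in (10.0, 15.0, 20.0, 25.0):
        m = build_monolayer(
            generate_hex_patch(PatchSpec(n_cells=20, noise_amplitude=0.25, seed=3))
        )
        run_simulation(
            m,
            MaterialParams(lambda_vol=lam),
            WoundProtocol(),
            SolverSettings(),
            RemeshSettings(),
            t_end=10.0,
            stop_on_closure=False,
        )
        devs.append(volume_deviation_stats(m)[1])
    assert all(a >= b for a, b in zip(devs, devs[1:]))
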