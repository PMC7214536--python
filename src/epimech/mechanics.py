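"""Energy, residual and tangent of the bar-network monolayer model.

Total energy

    W = W_N + W_V + W_Vol

with ``W_N = (k_N/2) Σ s_ij (l_ij − L_ij)²`` over nodal segments,
``W_V`` summing, per vertex segment, a viscoelastic branch
``(k_V/2) s (l − L)²`` whose rest length ``L`` remodels (see
:mod:`epimech.rheology`) and an elastic branch
``(k_V0/2) s L0 ((l − L0)/L0)² + k_V0 s Υ̂ l`` whose tension is the active
law ``σ_V = k_V0 (ε_e + Υ̂)``, and
``W_Vol = (λ_Vol/2) Σ ((V_i − V0_i)/V0_i)²`` over cells with the volume
penalty active.  ``s`` is the per-segment stiffness scale (0.01 inside
ablated cells, 1 otherwise).

Mechanical equilibrium is the stationarity of W with respect to the free
node positions and the relaxed/intermediate vertex positions; constrained
vertices contribute through the chain rule with interpolation weight 1/3
per parent node, which is what the point-to-DOF map encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import Mesh, SCHED_APICAL, SCHED_LATERAL, cell_volumes

__all__ = ["MaterialParams", "Assembly", "assemble", "active_tension", "residual_norm"]


class AssemblyError(RuntimeError):
    """Non-finite force or degenerate segment during assembly."""


@dataclass
class MaterialParams:
    """Material parameters of the monolayer (stiffnesses in model force
    units per model length; rates in 1/min; strains dimensionless).

    Defaults are the calibrated values: nodal stiffness ``k_N = 0.3``,
    viscoelastic-branch vertex stiffness ``k_V = 1.0``, elastic-branch
    vertex stiffness ``k_V0 = 0.05``, volume-penalty weight
    ``lambda_vol = 20``, intrinsic contractility ``eps_c = 1.3`` and
    rest-length remodelling rate ``gamma = 0.2`` (nodal segments do not
    remodel: their rate is 0, a purely elastic network).
    """

    k_N: float = 0.3
    k_V: float = 1.0
    k_V0: float = 0.05
    lambda_vol: float = 20.0
    eps_c: float = 1.3
    gamma: float = 0.2

    def __post_init__(self):
        for name in ("k_N", "k_V", "k_V0", "lambda_vol", "eps_c", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def active_tension(params: MaterialParams, l: float, L0: float, ups_hat: float) -> float:
    """Elastic-branch tension σ_V = k_V0 (ε_e + Υ̂) of a vertex segment.

    ``ε_e = (l − L0)/L0`` is the elastic strain relative to the segment's
    birth length and ``Υ̂`` the scheduled contractility (0 away from the
    wound edge).
    """
    return params.k_V0 * ((l - L0) / L0 + ups_hat)


@dataclass
class Assembly:
    energy: float
    grad: np.ndarray  # (3U,) gradient wrt free DOFs = residual forces
    hess: sp.csr_matrix | None
    lengths: np.ndarray
    L_eff: np.ndarray
    volumes: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.grad))


def _skew(v: np.ndarray) -> np.ndarray:
    """Stack of cross-product matrices: _skew(v)[n] @ x == cross(v[n], x)."""
    n = len(v)
    S = np.zeros((n, 3, 3))
    S[:, 0, 1] = -v[:, 2]
    S[:, 0, 2] = v[:, 1]
    S[:, 1, 0] = v[:, 2]
    S[:, 1, 2] = -v[:, 0]
    S[:, 2, 0] = -v[:, 1]
    S[:, 2, 1] = v[:, 0]
    return S


def schedule_array(mesh: Mesh, ups_apical: float, ups_lateral: float) -> np.ndarray:
    """Per-segment contractility Υ̂ from the wound-edge schedule values."""
    ups = np.zeros(len(mesh.seg_keys))
    ups[mesh.seg_sched == SCHED_APICAL] = ups_apical
    ups[mesh.seg_sched == SCHED_LATERAL] = ups_lateral
    return ups


def assemble(
    mesh: Mesh,
    u: np.ndarray,
    params: MaterialParams,
    *,
    ups: np.ndarray | None = None,
    rest_affine: tuple[np.ndarray, np.ndarray] | None = None,
    need_hess: bool = True,
) -> Assembly:
    """Evaluate energy, gradient and (optionally) the tangent at DOFs ``u``.

    ``rest_affine = (a, c)`` substitutes the implicit rest-length update
    ``L = a + c·l`` on remodelling (vertex) segments, so every evaluation
    sees rest lengths consistent with its trial geometry; the tangent then
    carries the extra ``dL/dl = c`` softening.  With ``rest_affine=None``
    rest lengths are frozen at the mesh's stored values, making the gradient
    exactly the derivative of the reported energy.
    """
    P = mesh.positions(u)
    nseg = len(mesh.seg_keys)
    if ups is None:
        ups = np.zeros(nseg)

    d = P[mesh.seg_p[:, 1]] - P[mesh.seg_p[:, 0]]
    l = np.linalg.norm(d, axis=1)
    if np.any(l < 1e-12):
        s = int(np.argmin(l))
        raise AssemblyError(f"segment {mesh.seg_keys[s]} has collapsed (l={l[s]:.3g})")
    dhat = d / l[:, None]

    isv = mesh.seg_is_vertex
    scale = mesh.seg_scale
    L = mesh.L.copy()
    dLdl = np.zeros(nseg)
    if rest_affine is not None:
        a, c = rest_affine
        L[isv] = a[isv] + c[isv] * l[isv]
        dLdl[isv] = c[isv]
    L0 = mesh.L0

    # tensions and tangent stiffnesses per segment
    f = np.where(
        isv,
        scale * (params.k_V * (l - L) + params.k_V0 * ((l - L0) / L0 + ups)),
        scale * params.k_N * (l - L),
    )
    kt = np.where(
        isv,
        scale * (params.k_V * (1.0 - dLdl) + params.k_V0 / L0),
        scale * params.k_N,
    )
    W_seg = np.where(
        isv,
        scale
        * (
            0.5 * params.k_V * (l - L) ** 2
            + 0.5 * params.k_V0 * (l - L0) ** 2 / L0
            + params.k_V0 * ups * l
        ),
        scale * 0.5 * params.k_N * (l - L) ** 2,
    )
    if not np.all(np.isfinite(f)):
        s = int(np.flatnonzero(~np.isfinite(f))[0])
        raise AssemblyError(f"non-finite force on segment {mesh.seg_keys[s]}")

    grad_P = np.zeros_like(P)
    np.add.at(grad_P, mesh.seg_p[:, 1], f[:, None] * dhat)
    np.add.at(grad_P, mesh.seg_p[:, 0], -f[:, None] * dhat)

    # ---- volume penalty --------------------------------------------------
    V = cell_volumes(mesh, P)
    V0 = mesh.cell_V0
    dev = (V - V0) / V0
    pen = mesh.cell_penalty
    W_vol = 0.5 * params.lambda_vol * float(np.sum(dev[pen] ** 2))
    coef = np.where(pen, params.lambda_vol * dev / V0, 0.0)  # dW/dV per cell

    q = P[mesh.tets]
    e1 = q[:, 1] - q[:, 0]
    e2 = q[:, 2] - q[:, 0]
    e3 = q[:, 3] - q[:, 0]
    g1 = np.cross(e2, e3) / 6.0
    g2 = np.cross(e3, e1) / 6.0
    g3 = np.cross(e1, e2) / 6.0
    g0 = -(g1 + g2 + g3)
    gv = np.stack([g0, g1, g2, g3], axis=1)  # (nt, 4, 3) = ∂V_tet/∂corner
    ct = coef[mesh.tet_cell]
    np.add.at(grad_P, mesh.tets.ravel(), (ct[:, None, None] * gv).reshape(-1, 3))

    energy = float(np.sum(W_seg)) + W_vol
    grad_u = mesh.A.T @ grad_P.ravel()

    hess = None
    if need_hess:
        nP = mesh.n_pts
        # segment blocks
        I3 = np.eye(3)
        outer = np.einsum("si,sj->sij", dhat, dhat)
        M = kt[:, None, None] * outer + (f / l)[:, None, None] * (I3 - outer)
        seg_blocks = np.empty((nseg, 2, 2, 3, 3))
        seg_blocks[:, 0, 0] = M
        seg_blocks[:, 1, 1] = M
        seg_blocks[:, 0, 1] = -M
        seg_blocks[:, 1, 0] = -M
        sp_idx = mesh.seg_p  # (nseg, 2)
        srows = (3 * sp_idx[:, :, None, None, None] + np.arange(3)[None, None, None, :, None])
        srows = np.broadcast_to(srows, (nseg, 2, 2, 3, 3))
        scols = (3 * sp_idx[:, None, :, None, None] + np.arange(3)[None, None, None, None, :])
        scols = np.broadcast_to(scols, (nseg, 2, 2, 3, 3))

        # tetrahedral volume Hessian: H_ab = ∂²V/∂q_a∂q_b, scaled by dW/dV
        nt = len(mesh.tets)
        Z = np.zeros((nt, 3, 3))
        S1, S2, S3 = _skew(e1), _skew(e2), _skew(e3)
        H = np.empty((nt, 4, 4, 3, 3))
        H[:, 1, 1] = Z
        H[:, 2, 2] = Z
        H[:, 3, 3] = Z
        H[:, 1, 2] = -S3 / 6.0
        H[:, 2, 1] = S3 / 6.0
        H[:, 1, 3] = S2 / 6.0
        H[:, 3, 1] = -S2 / 6.0
        H[:, 2, 3] = -S1 / 6.0
        H[:, 3, 2] = S1 / 6.0
        for a in (1, 2, 3):
            H[:, a, 0] = -(H[:, a, 1] + H[:, a, 2] + H[:, a, 3])
        for b2 in (1, 2, 3):
            H[:, 0, b2] = -(H[:, 1, b2] + H[:, 2, b2] + H[:, 3, b2])
        H[:, 0, 0] = -(H[:, 0, 1] + H[:, 0, 2] + H[:, 0, 3])
        H *= ct[:, None, None, None, None]
        trows = (3 * mesh.tets[:, :, None, None, None] + np.arange(3)[None, None, None, :, None])
        trows = np.broadcast_to(trows, (nt, 4, 4, 3, 3))
        tcols = (3 * mesh.tets[:, None, :, None, None] + np.arange(3)[None, None, None, None, :])
        tcols = np.broadcast_to(tcols, (nt, 4, 4, 3, 3))

        # per-cell rank-one ∇V ∇Vᵀ blocks
        ncell, Wd = mesh.cell_pts.shape
        gradC = np.zeros((ncell, Wd, 3))
        np.add.at(
            gradC,
            (mesh.tet_cell[:, None].repeat(4, 1).ravel(), mesh.tet_slot.ravel()),
            gv.reshape(-1, 3),
        )
        c1 = np.where(pen, params.lambda_vol / V0**2, 0.0)
        R = np.einsum("c,cai,cbj->caibj", c1, gradC, gradC)
        crows = (3 * mesh.cell_pts[:, :, None, None, None] + np.arange(3)[None, None, :, None, None])
        crows = np.broadcast_to(crows, (ncell, Wd, 3, Wd, 3))
        ccols = (3 * mesh.cell_pts[:, None, None, :, None] + np.arange(3)[None, None, None, None, :])
        ccols = np.broadcast_to(ccols, (ncell, Wd, 3, Wd, 3))

        rows = np.concatenate([srows.ravel(), trows.ravel(), crows.ravel()])
        cols = np.concatenate([scols.ravel(), tcols.ravel(), ccols.ravel()])
        valsv = np.concatenate([seg_blocks.ravel(), H.ravel(), R.ravel()])
        H_P = sp.coo_matrix((valsv, (rows, cols)), shape=(3 * nP, 3 * nP)).tocsr()
        hess = (mesh.A.T @ H_P @ mesh.A).tocsr()

    return Assembly(
        energy=energy, grad=grad_u, hess=hess, lengths=l, L_eff=L, volumes=V
    )


def residual_norm(mesh: Mesh, params: MaterialParams, **kw) -> float:
    """2-norm of the equilibrium residual at the mesh's current state."""
    return assemble(mesh, mesh.gather_u(), params, need_hess=False, **kw).norm
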