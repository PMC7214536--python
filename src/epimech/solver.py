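"""Time integration: implicit Newton–Raphson steps with line search.

Each time step solves mechanical equilibrium g(x, y_w) = 0 for the free
node and vertex positions with the θ-weighted rest-length update
substituted symbolically (so rest lengths stay consistent with the trial
geometry within every Newton iterate), converging to
``‖δx‖ < tol`` and ``‖g‖ < tol``.  Steps that fail to converge are retried
with a halved Δt; after a success the schedule Δt is restored.  Remeshing
happens only between converged steps, never inside Newton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import metrics
from .geometry import Monolayer
from .mechanics import AssemblyError, MaterialParams, assemble, schedule_array
from .remesh import RemeshSettings, remesh_step
from .rheology import rest_affine_coefficients
from .wound import WoundProtocol, contractility_schedule, maintain_wound

log = logging.getLogger("epimech")

__all__ = [
    "SolverSettings",
    "NewtonError",
    "SimulationAborted",
    "newton_solve",
    "run_simulation",
]

#: columns of the per-step time-series table
TIMESERIES_COLUMNS = [
    "t_min",
    "wound_area_um2",
    "rel_height",
    "n_edge_cells",
    "mean_vol_dev",
    "max_vol_dev",
    "newton_iters",
    "dt_min",
]


@dataclass
class SolverSettings:
    """θ-scheme weight, time-step schedule and Newton tolerances.

    Defaults: θ = 0.5 (second-order, unconditionally stable), Δt = 0.6 min
    during recoil (t ≤ recoil_end) and 1.0 min during closure, convergence
    tolerance 1e-10 on both ‖δx‖ and ‖g‖ (2-norms).
    """

    theta: float = 0.5
    dt_recoil: float = 0.6
    dt_closure: float = 1.0
    recoil_end: float = 6.0
    newton_tol: float = 1e-10
    max_newton_iters: int = 150
    max_halvings: int = 8
    armijo: float = 1e-4
    min_line_step: float = 2.0**-10
    step_tol: float = 1e-8
    max_step: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.dt_recoil <= 0 or self.dt_closure <= 0:
            raise ValueError("time steps must be positive")

    def dt_for(self, t: float) -> float:
        return self.dt_recoil if t < self.recoil_end - 1e-9 else self.dt_closure


class NewtonError(RuntimeError):
    """Newton did not reach the tolerance; the caller should halve Δt."""


class SimulationAborted(RuntimeError):
    def __init__(self, msg: str, timeseries: pd.DataFrame):
        super().__init__(msg)
        self.timeseries = timeseries


def newton_solve(
    m: Monolayer,
    params: MaterialParams,
    dt: float,
    settings: SolverSettings,
    ups: tuple[float, float] = (0.0, 0.0),
) -> int:
    """One implicit step: equilibrate positions and advance rest lengths.

    ``ups`` are the wound-edge contractility values (Υ̂_A^c, Υ̂_L^c) at the
    step's end time.  On success the state is updated in place (positions,
    relaxed/intermediate vertices, rest lengths) and the number of Newton
    iterations is returned.  Raises :class:`NewtonError` on failure, leaving
    the state untouched.
    """
    mesh = m.mesh()
    u0 = mesh.gather_u()
    ups_arr = schedule_array(mesh, *ups)

    # rest-length update coefficients from the state at t_n
    P = mesh.positions(u0)
    l_n = np.linalg.norm(P[mesh.seg_p[:, 1]] - P[mesh.seg_p[:, 0]], axis=1)
    # junctional (in-plane) vertex segments remodel toward the contractile
    # strain ε_c; lateral vertex segments are plain Maxwell (ε_c = 0)
    eps = np.where(mesh.seg_lateral, 0.0, params.eps_c)
    a, c = rest_affine_coefficients(
        l_n, mesh.L, dt, settings.theta, params.gamma, eps
    )
    affine = (a, c)

    def _eval(uv, need_hess=False):
        try:
            return assemble(
                mesh, uv, params, ups=ups_arr, rest_affine=affine, need_hess=need_hess
            )
        except AssemblyError as err:
            raise NewtonError(f"assembly failure: {err}") from err

    def _eval_or_none(uv):
        try:
            return assemble(
                mesh, uv, params, ups=ups_arr, rest_affine=affine, need_hess=False
            )
        except AssemblyError:
            return None

    u = u0.copy()
    asm = _eval(u)
    gnorm = asm.norm
    iters = 0
    last_step = 0.0
    mu = 0.0  # Levenberg damping, raised when the pure Newton step misbehaves
    while True:
        # convergence demands both a small residual and a stationary iterate
        if gnorm < settings.newton_tol and (iters == 0 or last_step < settings.step_tol):
            break
        if iters >= settings.max_newton_iters:
            raise NewtonError(f"no convergence in {iters} iterations (‖g‖={gnorm:.3e})")
        asm = _eval(u, need_hess=True)
        H = asm.hess
        dscale = float(np.abs(H.diagonal()).mean()) or 1.0
        accepted = False
        for _ in range(8):  # damping escalation
            Hd = H if mu == 0.0 else H + (mu * dscale) * sp.eye(H.shape[0], format="csr")
            try:
                delta = spla.spsolve(Hd.tocsc(), -asm.grad)
            except RuntimeError:
                delta = None
            if delta is None or not np.all(np.isfinite(delta)):
                mu = max(10.0 * mu, 1e-8)
                continue
            # trust region: cap wild excursions of near-singular tangents
            dn = float(np.linalg.norm(delta))
            if dn > settings.max_step:
                delta *= settings.max_step / dn
            # backtracking line search on the merit ½‖g‖²
            phi0 = 0.5 * gnorm**2
            alpha = 1.0
            while alpha >= settings.min_line_step:
                trial = _eval_or_none(u + alpha * delta)
                if trial is not None and (
                    0.5 * trial.norm**2 <= (1.0 - 2.0 * settings.armijo * alpha) * phi0
                ):
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                break
            mu = max(10.0 * mu, 1e-8)
        if not accepted:
            raise NewtonError(f"no descent direction found (‖g‖={gnorm:.3e}, μ={mu:.1e})")
        u = u + alpha * delta
        gnorm = trial.norm
        last_step = float(np.linalg.norm(alpha * delta))
        iters += 1
        mu *= 0.25  # relax damping toward pure Newton
        if mu < 1e-12:
            mu = 0.0

    # commit: positions, derived rest lengths
    mesh.scatter_u(u)
    P = mesh.positions(u)
    l = np.linalg.norm(P[mesh.seg_p[:, 1]] - P[mesh.seg_p[:, 0]], axis=1)
    isv = mesh.seg_is_vertex
    newL = mesh.L.copy()
    newL[isv] = a[isv] + c[isv] * l[isv]
    if np.any(newL[isv] <= 0):
        raise NewtonError("rest length driven non-positive")
    mesh.L = newL
    mesh.sync_rest_lengths()
    return iters


def run_simulation(
    m: Monolayer,
    params: MaterialParams,
    protocol: WoundProtocol,
    settings: SolverSettings,
    remesh_settings: RemeshSettings,
    t_end: float = 150.0,
    stop_on_closure: bool = True,
    frame_callback=None,
    event_log: list | None = None,
) -> pd.DataFrame:
    """Advance the wounded (or intact) monolayer to ``t_end`` minutes.

    Loop per increment: evaluate the contractility schedule at the step end
    time, converge the implicit solve (halving Δt on failure, up to
    ``max_halvings``, then aborting with partial output), re-triangulate
    both layers, run wound maintenance (cell removal, closure detection),
    record observables and optionally emit a frame.  Fully deterministic
    for a fixed initial state and configuration.
    """
    rows = []
    step = 0

    def _record(iters: int, dt: float):
        mean_dev, max_dev = metrics.volume_deviation_stats(m)
        n_edge, _ = metrics.wound_edge_counts(m)
        rows.append(
            {
                "t_min": m.time,
                "wound_area_um2": metrics.apical_wound_area(m),
                "rel_height": metrics.relative_height(m),
                "n_edge_cells": n_edge,
                "mean_vol_dev": mean_dev,
                "max_vol_dev": max_dev,
                "newton_iters": iters,
                "dt_min": dt,
            }
        )
        if frame_callback is not None:
            frame_callback(m, step)

    _record(0, 0.0)
    while m.time < t_end - 1e-9:
        dt_sched = settings.dt_for(m.time)
        dt = min(dt_sched, t_end - m.time)
        halvings = 0
        while True:
            backup = m.copy()
            ups = contractility_schedule(m.time + dt, protocol)
            try:
                iters = newton_solve(m, params, dt, settings, ups=ups)
                break
            except NewtonError as err:
                # restore and retry with a halved increment
                backup._mesh = None
                m.__dict__.update(backup.__dict__)
                m.invalidate_mesh()
                halvings += 1
                dt *= 0.5
                log.info("step %d: halving dt to %.4g (%s)", step, dt, err)
                if halvings > settings.max_halvings:
                    ts = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
                    raise SimulationAborted(
                        f"t={m.time:.2f} min: Newton failed after "
                        f"{halvings - 1} halvings ({err})",
                        ts,
                    ) from err
        m.time += dt
        step += 1
        try:
            events = remesh_step(m, remesh_settings)
            info = maintain_wound(m, protocol)
        except Exception as err:
            ts = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
            raise SimulationAborted(
                f"t={m.time:.2f} min: connectivity update failed ({err})", ts
            ) from err
        if events:
            log.debug("t=%.2f: %d T1 events", m.time, len(events))
            if event_log is not None:
                event_log.extend(
                    {"t_min": m.time, "layer": layer, "edge_a": e[0], "edge_b": e[1]}
                    for layer, e in events
                )
        if info["removed_cells"]:
            log.info("t=%.2f: removed degraded cells %s", m.time, info["removed_cells"])
        _record(iters, dt)
        if stop_on_closure and m.wound_closed:
            log.info("wound closed at t=%.2f min", m.time)
            break
    return pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
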