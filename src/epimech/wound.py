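"""In-silico wounding: ablation, purse-string schedules, wound maintenance.

Ablation degrades the stiffness of segments fully interior to the ablated
cells to 1% of nominal, removes their volume penalty, and releases the
barycentric constraint of wound-edge vertices (they become independent
unknowns, avoiding zig-zag artifacts at the perimeter).  From the
activation time t_w, an actomyosin purse-string is emulated by an extra
tension k_V0·Υ̂ on wound-edge segments: a linearly decaying amplitude on
apical perimeter segments (mimicking the measured Myosin II decay) and a
constant amplitude on wound-edge lateral segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    Monolayer,
    STATE_ABLATED,
    STATE_ALIVE,
    edges_of,
    polygon_area_xy,
)
from .remesh import remove_cell_node

__all__ = ["WoundProtocol", "ablate", "contractility_schedule", "maintain_wound"]


@dataclass
class WoundProtocol:
    """Ablation set and contractility schedule of a wound-healing run.

    ``Y_Ac``/``Y_Lc`` are the apical and lateral contractility amplitudes
    Υ_A^c, Υ_L^c; the apical one decays linearly over ``decay_span``
    (minutes) after activation at ``t_w``.  ``removal_area_fraction`` sets
    when a degraded cell is deleted (apical area below that fraction of the
    initial mean cell area) and ``closure_area_fraction`` when the wound is
    declared closed (area below that fraction of the post-recoil maximum).
    """

    ablated_cell_ids: tuple[int, ...] = ()
    t_ablate: float = 0.0
    stiffness_factor: float = 0.01
    t_w: float = 6.0
    Y_Ac: float = 2.3
    Y_Lc: float = 0.0
    decay_span: float = 400.0
    removal_area_fraction: float = 0.4
    closure_area_fraction: float = 0.25

    def __post_init__(self):
        if not 0.0 < self.stiffness_factor < 1.0:
            raise ValueError("stiffness_factor must lie in (0, 1)")
        if self.Y_Ac < 0 or self.Y_Lc < 0:
            raise ValueError("contractility amplitudes must be non-negative")
        if self.decay_span <= 0:
            raise ValueError("decay_span must be positive")


def ablate(m: Monolayer, protocol: WoundProtocol) -> Monolayer:
    """Mark the protocol's cells as ablated (in place; returns the state).

    The ablated set must be interior (none of the fixed boundary cells) and
    edge-connected in the apical triangulation.  Ablating an empty set is a
    no-op.  The stiffness degradation and volume-penalty removal take
    effect through the mesh rebuild.
    """
    ids = sorted(int(i) for i in protocol.ablated_cell_ids)
    if not ids:
        return m
    for i in ids:
        if not 0 <= i < m.n_nodes or m.cell_state[i] != STATE_ALIVE:
            raise ValueError(f"cell {i} cannot be ablated (not a live cell)")
        if m.is_fixed[i] or m.is_ring[i]:
            raise ValueError(
                f"cell {i} is on the fixed patch boundary and cannot be ablated"
            )
    # connectivity in the apical edge graph
    edges = edges_of(m.tri_a)
    idset = set(ids)
    adj = {i: set() for i in ids}
    for a, b in edges:
        if a in idset and b in idset:
            adj[a].add(b)
            adj[b].add(a)
    seen = {ids[0]}
    stack = [ids[0]]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if seen != idset:
        raise ValueError("ablated set is not edge-connected")
    m.cell_state[ids] = STATE_ABLATED
    m.ablated_scale = protocol.stiffness_factor
    m.wound_closed = False
    m.wound_max_area = 0.0
    m.invalidate_mesh()
    return m


def contractility_schedule(t: float, protocol: WoundProtocol) -> tuple[float, float]:
    """Schedule values (Υ̂_A^c, Υ̂_L^c) at time t (minutes post-ablation).

    Apical: Y_Ac (1 − (t − t_w)/decay_span) for t > t_w, clamped at zero;
    lateral: constant Y_Lc for t > t_w; both zero otherwise.
    """
    if t <= protocol.t_w:
        return 0.0, 0.0
    ups_a = protocol.Y_Ac * (1.0 - (t - protocol.t_w) / protocol.decay_span)
    return max(ups_a, 0.0), protocol.Y_Lc


def wound_area(m: Monolayer) -> float:
    """Projected apical wound area in model units² (0 once closed)."""
    if m.wound_closed:
        return 0.0
    mesh = m.mesh()
    P = mesh.positions()
    area = 0.0
    for ci, i in enumerate(mesh.cells):
        if m.cell_state[i] == STATE_ABLATED:
            area += polygon_area_xy(P, mesh.cell_apical_loop[ci])
    return area


def maintain_wound(m: Monolayer, protocol: WoundProtocol) -> dict:
    """Per-step wound bookkeeping, called after remeshing.

    Degraded cells whose apical polygon area has dropped below
    ``removal_area_fraction`` of the initial mean cell area are removed
    (their node leaves both triangulations and the cavity is
    re-triangulated); the wound is declared closed — a latching flag — when
    the apical wound area falls below ``closure_area_fraction`` of the
    post-recoil maximum, or when no ablated cell remains.
    """
    removed: list[int] = []
    if not m.wound_closed:
        threshold = protocol.removal_area_fraction * m.init_mean_cell_area
        # progressive clearance: at most one cell per step, so the solver
        # re-equilibrates between the volume shocks of successive removals
        mesh = m.mesh()
        P = mesh.positions()
        worst = None
        for ci, i in enumerate(mesh.cells):
            if m.cell_state[i] != STATE_ABLATED:
                continue
            a = polygon_area_xy(P, mesh.cell_apical_loop[ci])
            if a < threshold and (worst is None or a < worst[0]):
                worst = (a, int(i))
        if worst is not None:
            remove_cell_node(m, worst[1])
            removed.append(worst[1])

    area = wound_area(m)
    m.wound_max_area = max(m.wound_max_area, area)
    n_ablated = int(np.sum(m.cell_state == STATE_ABLATED))
    if not m.wound_closed:
        if n_ablated == 0 and len(removed) > 0:
            m.wound_closed = True  # the last degraded cell was resorbed
        elif (
            m.wound_max_area > 0
            and area < protocol.closure_area_fraction * m.wound_max_area
        ):
            m.wound_closed = True
    return {
        "removed_cells": removed,
        "wound_area": 0.0 if m.wound_closed else area,
        "closed": m.wound_closed,
        "n_ablated": n_ablated,
    }
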