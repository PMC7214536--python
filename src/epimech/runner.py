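"""High-level drivers: configuration → patch → wound → simulation → summary."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import patchgen
from .config import RunConfig, dump_config
from .geometry import Monolayer, build_monolayer
from .solver import SimulationAborted, run_simulation
from .wound import WoundProtocol, ablate

__all__ = ["prepare_state", "run_from_config", "summarize"]


def prepare_state(cfg: RunConfig):
    """Generate the patch, build and pre-equilibrate the monolayer, ablate.

    Before wounding, the intact patch is settled for ``presettle_min``
    minutes: the viscoelastic rest lengths remodel toward the intrinsic
    contractile strain ε_c, building the homeostatic junctional prestress
    that a living epithelium carries.  Ablation then releases that tension
    at the wound, which is what produces the recoil (a stress-free patch
    would show none).  The clock is reset to 0 at ablation.

    Returns ``(monolayer, params, protocol, solver_settings, remesh_settings)``.
    """
    spec = cfg.patch.to_spec(cfg.seed)
    centers = patchgen.generate_hex_patch(spec)
    m = build_monolayer(
        centers, height_um=cfg.patch.height_um, length_unit_um=cfg.length_unit_um
    )
    params = cfg.material.to_params()
    solver_settings = cfg.solver.to_settings()
    remesh_settings = cfg.remesh.to_settings()
    if cfg.presettle_min > 0:
        run_simulation(
            m,
            params,
            WoundProtocol(),  # intact: no ablation, schedules never active
            solver_settings,
            remesh_settings,
            t_end=cfg.presettle_min,
            stop_on_closure=False,
        )
        m.time = 0.0
    if cfg.wound.n_ablate > 0:
        ids = patchgen.select_ablation_region(centers, cfg.wound.n_ablate)
    else:
        ids = set()
    protocol = cfg.wound.to_protocol(ids)
    if ids:
        ablate(m, protocol)
    return m, params, protocol, solver_settings, remesh_settings


def summarize(ts: pd.DataFrame, m: Monolayer, aborted: str | None = None) -> dict:
    """Run summary: closure state/time, recoil maximum, final height."""
    closed = bool(m.wound_closed)
    closure_time = float(ts.loc[ts.index[-1], "t_min"]) if closed else None
    return {
        "closed": closed,
        "closure_time_min": closure_time,
        "recoil_area_um2": float(ts["wound_area_um2"].max()),
        "final_wound_area_um2": float(ts["wound_area_um2"].iloc[-1]),
        "final_rel_height": float(ts["rel_height"].iloc[-1]),
        "max_mean_vol_dev": float(ts["mean_vol_dev"].max()),
        "n_steps": int(len(ts) - 1),
        "t_final_min": float(ts["t_min"].iloc[-1]),
        "aborted": aborted,
    }


def run_from_config(cfg: RunConfig, outdir: str | None = None, frame_callback=None):
    """Run one simulation; returns ``(timeseries, summary, monolayer)``.

    A non-converging run (the model's own failure mode at pathological
    parameters, e.g. extreme volume-penalty weights) is reported in the
    summary rather than raised, with partial outputs retained.
    """
    m, params, protocol, solver_settings, remesh_settings = prepare_state(cfg)
    writer = frame_callback
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dump_config(cfg, out / "config.yaml")
        if cfg.frame_every > 0 and writer is None:
            from . import metrics as _metrics
            from .vtkio import write_frame

            def writer(state, step):  # noqa: F811
                if step % cfg.frame_every == 0:
                    write_frame(state, out / f"frame_{step:04d}.vtk")
                    loops = _metrics.wound_perimeter_loops(state)
                    if loops:
                        rows = []
                        for li, loop in enumerate(loops):
                            for p in loop:
                                rows.append(f"{li},{p[0]:.6g},{p[1]:.6g},{p[2]:.6g}")
                        (out / f"wound_{step:04d}.csv").write_text(
                            "loop,x_um,y_um,z_um\n" + "\n".join(rows) + "\n"
                        )

    aborted = None
    events: list = []
    try:
        ts = run_simulation(
            m,
            params,
            protocol,
            solver_settings,
            remesh_settings,
            t_end=cfg.t_end_min,
            stop_on_closure=cfg.stop_on_closure,
            frame_callback=writer,
            event_log=events,
        )
    except SimulationAborted as err:
        ts = err.timeseries
        aborted = str(err)
    summary = summarize(ts, m, aborted=aborted)
    if outdir is not None:
        ts.to_csv(Path(outdir) / "timeseries.csv", index=False)
        (Path(outdir) / "summary.json").write_text(json.dumps(summary, indent=2))
        pd.DataFrame(events, columns=["t_min", "layer", "edge_a", "edge_b"]).to_csv(
            Path(outdir) / "t1_events.csv", index=False
        )
    return ts, summary, m
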