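"""Calibration-style parameter studies: recoil sensitivity and the closure
threshold in apical purse-string contractility."""

from __future__ import annotations

import logging

from .config import RunConfig
from .runner import run_from_config

log = logging.getLogger("epimech")

__all__ = ["recoil_area_at", "recoil_sensitivity_study", "closure_threshold_search"]

_PARAM_PATHS = {
    "eps_c": ("material", "eps_c"),
    "gamma": ("material", "gamma"),
    "k_V0": ("material", "k_V0"),
    "k_V": ("material", "k_V"),
    "k_N": ("material", "k_N"),
    "lambda_vol": ("material", "lambda_vol"),
    "Y_Ac": ("wound", "Y_Ac"),
    "Y_Lc": ("wound", "Y_Lc"),
}


def _with_param(cfg: RunConfig, name: str, value: float) -> RunConfig:
    if name not in _PARAM_PATHS:
        raise KeyError(f"unknown sweep parameter {name!r}; one of {sorted(_PARAM_PATHS)}")
    section, attr = _PARAM_PATHS[name]
    out = cfg.model_copy(deep=True)
    setattr(getattr(out, section), attr, value)
    return out


def recoil_area_at(cfg: RunConfig, t_recoil: float = 6.0) -> float | None:
    """Apical wound area (μm²) at the end of the recoil phase.

    Runs the wounded configuration to ``t_recoil`` minutes (no purse-string
    active yet) and reports the final wound area; ``None`` if the run fails
    to converge.
    """
    c = cfg.model_copy(deep=True)
    c.t_end_min = t_recoil
    ts, summary, _ = run_from_config(c)
    if summary["aborted"]:
        return None
    return float(ts["wound_area_um2"].iloc[-1])


def recoil_sensitivity_study(cfg: RunConfig, parameter: str, grid) -> list[float | None]:
    """Recoil area at t = 6 min for each value of one material parameter.

    Expected trends on the calibration patch: the recoil area increases
    with the intrinsic contractility ε_c and with the remodelling rate γ,
    and decreases with the elastic vertex stiffness k_V0.  Non-converged
    grid points report ``None``.
    """
    out = []
    for v in grid:
        out.append(recoil_area_at(_with_param(cfg, parameter, float(v))))
        log.info("recoil study %s=%.4g -> %s", parameter, v, out[-1])
    return out


def closure_threshold_search(
    cfg: RunConfig,
    bracket: tuple[float, float] = (1.5, 3.0),
    resolution: float = 0.1,
) -> float:
    """Smallest apical contractility Y_Ac that closes the wound.

    Bisection at ``resolution`` on the closed/not-closed outcome over the
    bracket (endpoints must straddle the transition: low fails, high
    closes).  A run that fails to converge counts as not closing.  Relies
    on the monotonicity of closure in Y_Ac, so the result equals a full
    grid scan at the same resolution.
    """
    lo, hi = bracket

    def _closes(y: float) -> bool:
        _, summary, _ = run_from_config(_with_param(cfg, "Y_Ac", y))
        log.info("threshold search Y_Ac=%.3g -> closed=%s", y, summary["closed"])
        return bool(summary["closed"])

    n = int(round((hi - lo) / resolution))
    grid = [lo + k * resolution for k in range(n + 1)]
    if _closes(grid[0]):
        raise ValueError(f"lower bracket Y_Ac={lo} already closes; widen the bracket")
    if not _closes(grid[-1]):
        raise ValueError(f"upper bracket Y_Ac={hi} fails to close; widen the bracket")
    a, b = 0, n  # grid[a] fails, grid[b] closes
    while b - a > 1:
        mid = (a + b) // 2
        if _closes(grid[mid]):
            b = mid
        else:
            a = mid
    return float(grid[b])
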