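"""Run configuration: YAML-backed, validated, with the calibrated defaults.

An empty file (or ``RunConfig()``) resolves to the calibrated parameter set:
k_N = 0.3, k_V = 1.0, k_V0 = 0.05, λ_Vol = 20, ε_c = 1.3, γ = 0.2, θ = 0.5,
Δt = 0.6/1.0 min, tol = 1e-10, t_w = 6 min, apical decay span 400 min.
Unknown keys are rejected with itemised errors.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .mechanics import MaterialParams
from .patchgen import PatchSpec
from .remesh import RemeshSettings
from .solver import SolverSettings
from .wound import WoundProtocol

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PatchConfig(_Strict):
    n_cells: int = Field(205, ge=7)
    patch_side_um: float | None = Field(None, gt=0)
    noise_amplitude: float = Field(0.2, ge=0, lt=0.5)
    height_um: float = Field(35.0, gt=0)
    spacing_um: float = Field(9.0, gt=0)

    def to_spec(self, seed: int) -> PatchSpec:
        return PatchSpec(
            n_cells=self.n_cells,
            patch_side=self.patch_side_um,
            noise_amplitude=self.noise_amplitude,
            height=self.height_um,
            seed=seed,
            spacing=self.spacing_um,
        )


class MaterialConfig(_Strict):
    k_N: float = Field(0.3, ge=0)
    k_V: float = Field(1.0, ge=0)
    k_V0: float = Field(0.05, ge=0)
    lambda_vol: float = Field(20.0, ge=0)
    eps_c: float = Field(1.3, ge=0)
    gamma: float = Field(0.2, ge=0)

    def to_params(self) -> MaterialParams:
        return MaterialParams(**self.model_dump())


class SolverConfig(_Strict):
    theta: float = Field(0.5, ge=0, le=1)
    dt_recoil_min: float = Field(0.6, gt=0)
    dt_closure_min: float = Field(1.0, gt=0)
    recoil_end_min: float = Field(6.0, gt=0)
    newton_tol: float = Field(1e-10, gt=0)
    max_newton_iters: int = Field(150, gt=0)
    max_halvings: int = Field(8, ge=0)

    def to_settings(self) -> SolverSettings:
        return SolverSettings(
            theta=self.theta,
            dt_recoil=self.dt_recoil_min,
            dt_closure=self.dt_closure_min,
            recoil_end=self.recoil_end_min,
            newton_tol=self.newton_tol,
            max_newton_iters=self.max_newton_iters,
            max_halvings=self.max_halvings,
        )


class RemeshConfig(_Strict):
    tol_r: float = Field(0.3, ge=0)
    max_flips: int = Field(200, gt=0)
    force_equal_layers: bool = False
    junction_collapse_fraction: float = Field(0.25, ge=0, lt=1)

    def to_settings(self) -> RemeshSettings:
        return RemeshSettings(**self.model_dump())


class WoundConfig(_Strict):
    n_ablate: int = Field(8, ge=0)  # 0 = unwounded control
    t_w_min: float = Field(6.0, ge=0)
    Y_Ac: float = Field(2.3, ge=0)
    Y_Lc: float = Field(0.0, ge=0)
    decay_span_min: float = Field(400.0, gt=0)
    removal_area_fraction: float = Field(0.4, gt=0, lt=1)
    closure_area_fraction: float = Field(0.25, gt=0, lt=1)
    stiffness_factor: float = Field(0.01, gt=0, lt=1)

    def to_protocol(self, ablated_ids) -> WoundProtocol:
        return WoundProtocol(
            ablated_cell_ids=tuple(sorted(int(i) for i in ablated_ids)),
            t_w=self.t_w_min,
            Y_Ac=self.Y_Ac,
            Y_Lc=self.Y_Lc,
            decay_span=self.decay_span_min,
            removal_area_fraction=self.removal_area_fraction,
            closure_area_fraction=self.closure_area_fraction,
            stiffness_factor=self.stiffness_factor,
        )


class RunConfig(_Strict):
    seed: int = 0
    t_end_min: float = Field(150.0, gt=0)
    presettle_min: float = Field(30.0, ge=0)
    length_unit_um: float = Field(60.0, gt=0)
    stop_on_closure: bool = True
    frame_every: int = Field(0, ge=0)  # 0 disables frame output
    patch: PatchConfig = Field(default_factory=PatchConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    remesh: RemeshConfig = Field(default_factory=RemeshConfig)
    wound: WoundConfig = Field(default_factory=WoundConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file → defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration (all defaults expanded)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
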