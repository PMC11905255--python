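"""YAML run configuration with strict schema validation.

A :class:`RunConfig` describes a full synthetic experiment: grid, beams,
cameras, noise, scatter, solver and evaluation criteria.  Validation is
strict — unknown keys are rejected before any computation — and a single
global seed is split deterministically into per-stage streams.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .evaluation import GammaCriteria
from .grid import GridSpec, make_grid
from .optics import CalibrationRegion, CameraModel
from .phantom import BeamSpec, NoiseModel
from .reconstruction import SolverConfig

__all__ = ["RunConfig", "load_config", "split_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridCfg(_Strict):
    shape: tuple[int, int, int] = (100, 100, 100)
    voxel_size_mm: float | tuple[float, float, float] = 1.0
    origin_mm: Optional[tuple[float, float, float]] = None

    def build(self) -> GridSpec:
        return make_grid(self.shape, self.voxel_size_mm, self.origin_mm)


class BeamCfg(_Strict):
    gantry_angle_deg: float = 270.0
    field_size_mm: tuple[float, float] = (80.0, 80.0)
    penumbra_sigma_mm: float = 3.0
    attenuation_mu_per_mm: float = 0.005
    weight: float = 1.0
    duration_s: float = 1.0

    def build(self) -> BeamSpec:
        return BeamSpec(
            gantry_angle=self.gantry_angle_deg,
            field_size=self.field_size_mm,
            penumbra_sigma=self.penumbra_sigma_mm,
            attenuation_mu=self.attenuation_mu_per_mm,
            weight=self.weight,
            duration=self.duration_s,
        )


class CameraCfg(_Strict):
    id: str
    view_axis: str = "+z"
    pixel_shape: tuple[int, int] = (100, 100)
    pixel_pitch_mm: float = 1.0
    attenuation_lambda_per_mm: float = 0.0
    scatter_fraction: float = 0.0
    projection_mode: Literal["parallel", "pinhole"] = "parallel"
    focal_length_mm: Optional[float] = None
    gain: float = 1.0

    def build(self) -> CameraModel:
        return CameraModel(
            id=self.id,
            view_axis=self.view_axis,
            pixel_shape=self.pixel_shape,
            pixel_pitch=self.pixel_pitch_mm,
            attenuation_lambda=self.attenuation_lambda_per_mm,
            scatter_fraction=self.scatter_fraction,
            projection_mode=self.projection_mode,
            focal_length=self.focal_length_mm,
            gain=self.gain,
        )


class NoiseCfg(_Strict):
    poisson_gain: float = 1e4
    read_sigma: float = 0.0

    def build(self, seed: int) -> NoiseModel:
        return NoiseModel(poisson_gain=self.poisson_gain, read_sigma=self.read_sigma,
                          seed=seed)


class SolverCfg(_Strict):
    alpha: Optional[float] = None
    beta: Optional[float] = None
    max_iters: int = 300
    tol: float = 1e-7
    tv_flavor: Literal["isotropic", "anisotropic"] = "isotropic"
    tv_iters: int = 10
    nonneg: bool = True

    def build(self, seed: int = 0) -> SolverConfig:
        return SolverConfig(
            alpha=self.alpha, beta=self.beta, max_iters=self.max_iters, tol=self.tol,
            tv_flavor=self.tv_flavor, tv_iters=self.tv_iters, nonneg=self.nonneg,
            seed=seed,
        )


class CriteriaCfg(_Strict):
    dose_tolerance: float = 0.03
    distance_tolerance_mm: float = 3.0
    low_dose_threshold: float = 0.05
    normalization: Literal["global", "local"] = "global"

    def build(self) -> GammaCriteria:
        return GammaCriteria(
            dose_tolerance=self.dose_tolerance,
            distance_tolerance=self.distance_tolerance_mm,
            low_dose_threshold=self.low_dose_threshold,
            normalization=self.normalization,
        )


class ReferenceCfg(_Strict):
    """The square calibration field of known dose."""

    field_size_mm: tuple[float, float] = (80.0, 80.0)
    penumbra_sigma_mm: float = 3.0
    attenuation_mu_per_mm: float = 0.005
    weight: float = 1.0

    def build(self) -> BeamSpec:
        return BeamSpec(
            gantry_angle=270.0,
            field_size=self.field_size_mm,
            penumbra_sigma=self.penumbra_sigma_mm,
            attenuation_mu=self.attenuation_mu_per_mm,
            weight=self.weight,
            duration=1.0,
        )


class CalibrationCfg(_Strict):
    region_width_mm: float = 50.0
    region_height_mm: float = 50.0
    axis: Literal["x", "y", "z"] = "z"
    coordinate_mm: float = 0.0

    def build(self) -> CalibrationRegion:
        return CalibrationRegion(
            width=self.region_width_mm, height=self.region_height_mm,
            axis=self.axis, coordinate=self.coordinate_mm,
        )


class RunConfig(_Strict):
    """Top-level configuration for the simulate / full-qa workflows."""

    grid: GridCfg = Field(default_factory=GridCfg)
    beams: list[BeamCfg] = Field(default_factory=lambda: [BeamCfg()])
    cameras: list[CameraCfg] = Field(
        default_factory=lambda: [
            CameraCfg(id="cam_top", view_axis="+z"),
            CameraCfg(id="cam_front", view_axis="-y"),
            CameraCfg(id="cam_side", view_axis="+x"),
        ]
    )
    noise: NoiseCfg = Field(default_factory=NoiseCfg)
    solver: SolverCfg = Field(default_factory=SolverCfg)
    criteria: CriteriaCfg = Field(default_factory=CriteriaCfg)
    reference: ReferenceCfg = Field(default_factory=ReferenceCfg)
    calibration: CalibrationCfg = Field(default_factory=CalibrationCfg)
    scatter_fraction: float = 0.0
    frame_rate_hz: float = 1.0
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig.model_validate(data)


def split_seed(seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent sub-seeds (< 2**31) from a
    global seed via numpy's SeedSequence spawning."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]
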