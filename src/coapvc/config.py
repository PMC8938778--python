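"""Run configuration: validated YAML schema for the validation pipeline.

Unknown keys are rejected with a message (pydantic ``extra="forbid"``), so
typos fail before any computation starts.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigurationError
from .phantom import InjectionModel, NoiseModel, PhantomSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InjectionConfig(_Strict):
    injected_activity_mbq: float = 22.0
    injection_rate_ml_s: float = 0.5
    injection_duration_s: float = 50.0
    chamber_volume_ml: float = 150.0
    buffer_volume_ml: float = 500.0
    sample_dt_s: float = 0.5


class NoiseConfig(_Strict):
    kind: str = "none"
    scale: float = 1.0
    floor: float = 0.1


class TubeConfig(_Strict):
    diameter_mm: float
    center_xy_mm: tuple[float, float]
    role: str = "artery"


class PhantomConfig(_Strict):
    background_activity: float = 1.4  # kBq/cc
    psf_fwhm_mm: float = 6.0
    voxel_size_mm: float = 1.0
    fov_mm: tuple[float, float, float] = (310.0, 100.0, 60.0)
    tubes: list[TubeConfig] | None = None  # None -> the default tube bank
    n_frames: int = 15
    frame_duration_s: float = 20.0
    flow_rate_ml_s: float = 10.0
    tracer_half_life_min: float = 109.77
    decay_corrected: bool = True
    injection: InjectionConfig = Field(default_factory=InjectionConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)

    def to_spec(self, seed: int = 0) -> PhantomSpec:
        from .phantom import TubeSpec, default_frame_schedule, default_tube_bank

        bank = (default_tube_bank() if self.tubes is None else tuple(
            TubeSpec(t.diameter_mm, tuple(t.center_xy_mm), t.role)
            for t in self.tubes))
        return PhantomSpec(
            tube_bank=bank,
            background_activity=self.background_activity,
            psf_fwhm_mm=self.psf_fwhm_mm,
            voxel_size_mm=self.voxel_size_mm,
            fov_mm=self.fov_mm,
            frame_schedule=default_frame_schedule(self.n_frames, self.frame_duration_s),
            injection=InjectionModel(**self.injection.model_dump()),
            flow_rate_ml_s=self.flow_rate_ml_s,
            noise=NoiseModel(**self.noise.model_dump()),
            seed=seed,
            tracer_half_life_min=self.tracer_half_life_min,
            decay_corrected=self.decay_corrected,
        )


class RegionConfig(_Strict):
    spill_margin_mm: float = 15.0
    bkg_margin_mm: float = 10.0
    combined_radius_mm: float = 25.0
    roi_length_mm: float = 20.0
    replicates: int = 1
    weighting: str = "fractional"  # fractional | binary


class CorrectionConfig(_Strict):
    methods: tuple[str, ...] = ("simple", "background", "artery-vein", "rc")
    clamp_negative: bool = False


class KineticsConfig(_Strict):
    enabled: bool = False
    # synthetic tumour used for the AIF-impact demonstration
    true_k1: float = 0.1352
    true_k2: float = 0.0965
    true_k3: float = 0.0071


class RunConfig(_Strict):
    """Top-level run configuration for ``coapvc validate``."""

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    regions: RegionConfig = Field(default_factory=RegionConfig)
    correction: CorrectionConfig = Field(default_factory=CorrectionConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid run configuration {path}: {exc}") from exc
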