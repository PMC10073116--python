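"""Validated experiment configuration.

A single config object describes the acquisition grid, the phantom, the
medium, the dispersion screens and the processing pipeline. Unknown keys are
rejected (a silent typo would invalidate a science run) and every output is
stamped with a hash of the canonical serialized config. All randomness flows
from one root seed through named substreams (phantom, speckle, dispersion).
"""

from __future__ import annotations

import hashlib
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "GridConfig",
    "PhantomConfig",
    "MediumConfig",
    "DispersionConfig",
    "PipelineConfig",
    "ExperimentConfig",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    lambda_min_nm: float = 542.5
    lambda_max_nm: float = 752.5
    step_nm: float = 7.5
    subband_nm: float = 15.0
    n_illuminations: int = Field(49, ge=1)
    field_of_view_um: float = Field(4.2, gt=0)
    pixels_per_side: int = Field(32, ge=4)
    numerical_aperture: float = Field(1.0, gt=0)
    medium_index: float = Field(1.4, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.pixels_per_side % 2:
            raise ValueError("pixels_per_side must be even")
        if self.numerical_aperture > self.medium_index:
            raise ValueError("NA must not exceed the medium index")
        return self


class PhantomConfig(_Strict):
    kind: Literal[
        "siemens_star", "bar_target", "point_array", "random_particles", "mirror"
    ] = "point_array"
    depths_um: list[float] = [0.0]
    reflectivity: float = Field(1.0, gt=0)
    n_spokes: int = 8
    n_points: int = 5
    particle_density_per_um2: float = 0.15
    particle_diameter_um: float = 0.5


class MediumConfig(_Strict):
    ls_table_nm_um: list[tuple[float, float]] = [(535.0, 56.1), (760.0, 83.1)]
    anisotropy_g: float = Field(0.0, ge=0, lt=1)
    multiple_scatter_power: float = Field(0.0, ge=0)
    ms_depth_correlation: float = Field(0.0, ge=0, le=1)
    ms_depth_span_um: float = Field(16.0, gt=0)


class DispersionConfig(_Strict):
    strength_rad: float = Field(0.0, ge=0)
    correlation_length: float = Field(0.25, gt=0)
    spectral_model: Literal["separable", "polynomial_in_inv_lambda", "none"] = "separable"
    residual_strength_rad: float = Field(0.0, ge=0)
    residual_correlation_length: float = Field(0.3, gt=0)


class PipelineConfig(_Strict):
    mode: Literal[
        "reconstruct", "correct", "bandwidth_sweep", "progressive", "multidepth"
    ] = "reconstruct"
    target_depth_um: float = 0.0
    scan_z0_um: Optional[float] = None
    scan_z1_um: Optional[float] = None
    scan_dz_um: float = Field(0.25, gt=0)
    outer_iters: int = Field(3, ge=1)
    normalize: bool = False
    use_truth_reference: bool = True
    z_upper_um: float = -3.0
    z_lower_um: float = 3.0
    n_depths: int = Field(8, ge=1)
    depth_spacing_um: float = Field(1.7, gt=0)


class ExperimentConfig(_Strict):
    grid: GridConfig = GridConfig()
    phantom: PhantomConfig = PhantomConfig()
    medium: MediumConfig = MediumConfig()
    dispersion: DispersionConfig = DispersionConfig()
    pipeline: PipelineConfig = PipelineConfig()
    seed: int = Field(0, ge=0)
    output_dir: str = "vrm_output"

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        canon = self.model_dump_json()
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def substream(self, name: str) -> np.random.SeedSequence:
        """Named child seed sequence of the root seed."""
        names = {"phantom": 0, "speckle": 1, "dispersion": 2, "residual": 3}
        if name not in names:
            raise KeyError(f"unknown substream {name!r}")
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(names[name],))

    def substream_seed(self, name: str) -> int:
        """Single integer (< 2^31) drawn from the named substream."""
        return int(self.substream(name).generate_state(1, dtype=np.uint32)[0] % (2**31))
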