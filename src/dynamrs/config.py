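"""Declarative run configuration.

A :class:`RunConfig` captures every stage parameter of the pipeline — grid
and frame counts, ranks, ppm windows, fit-window boundaries, the Whittaker
penalty, the LP order, zero-fill dims and the seed — as a validated document.
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["WindowConfig", "RunConfig"]


class WindowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    center: float
    half_width: float = Field(gt=0)


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (all ppm / s / min units)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: Literal[1] = 1
    seed: int = 0

    # phantom / simulation
    grid: tuple[int, int] = (8, 8)
    noise_sigma: float = Field(default=50.0, ge=0)
    phase0: float = 0.0
    phase1: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    duration_s: float = Field(default=3600.0, gt=0)
    frame_spacing_s: float = Field(default=16.0, gt=0)
    csi_n_frames: int = Field(default=75, ge=1)
    csi_frame_spacing_s: float = Field(default=48.0, gt=0)

    # preprocessing
    dead_time_points: int = Field(default=67, ge=0)
    lp_order: int = Field(default=16, ge=1)
    lp_n_out: int = Field(default=1024, ge=1)
    whittaker_lambda: float = Field(default=1e7, ge=0)
    dietrich_c: float = Field(default=3.0, gt=0)

    # denoising
    matrix_rank: int = Field(default=5, ge=1)
    tensor_ranks: tuple[int, int, int, int] = (6, 6, 8, 8)

    # kinetics
    t0_min: float = Field(default=5.0, gt=0)
    decay_start_min: float = Field(default=25.0, gt=0)
    windows: dict[str, WindowConfig] = Field(
        default_factory=lambda: {
            "glucose": WindowConfig(center=98.0, half_width=1.5),
            "lactate": WindowConfig(center=23.0, half_width=1.5),
            "noise": WindowConfig(center=150.0, half_width=15.0),
        }
    )

    # imaging
    zero_fill: tuple[int, int] = (16, 16)
    snr_min: float = Field(default=5.0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.decay_start_min <= self.t0_min:
            raise ValueError("decay_start_min must exceed t0_min")
        if any(r < 1 for r in self.tensor_ranks):
            raise ValueError("tensor ranks must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full document; embedded in every output."""
        blob = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
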