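"""Validated run configuration for the simulation/reconstruction pipeline.

Presets: ``desk`` (32x32 matrix, 16 rings, 128 points/ring, 8 coils, 64
spectral points — seconds-scale, used by the test suite), ``full`` (64x64,
32 rings, 540 points/ring, 32 coils, 882 spectral points at 2778 Hz — the
full single-slice acquisition geometry), and ``tiny`` (smoke-test scale).
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

__all__ = ["RunConfig", "preset", "PRESETS"]

# Water-reference excitation relative to the MRSI excitation: the
# interleaved calibration uses a 5 deg flip, the standalone prescans 13 deg,
# versus 42 deg for the metabolite scan.
FLIP_SCALES = {
    "imusical": math.sin(math.radians(5)) / math.sin(math.radians(42)),
    "static": math.sin(math.radians(13)) / math.sin(math.radians(42)),
    "moved": math.sin(math.radians(13)) / math.sin(math.radians(42)),
}
# Head rotation of the object during each calibration acquisition: the
# interleaved scan shares the MRSI head position exactly; a standalone
# prescan carries a small repositioning drift; the "moved" prescan follows
# an instructed ~15 deg rotation.
DEFAULT_ROTATIONS = {"imusical": 0.0, "static": 3.0, "moved": 15.0}


class GeometryConfig(BaseModel):
    matrix_size: int = 32
    n_rings: int = 16
    points_per_ring: int = 128
    n_coils: int = 8
    n_spec: int = 64
    spectral_bandwidth: float = 2778.0
    fov: float = 220.0
    noise_sd: float = 8.0

    @property
    def dwell(self) -> float:
        return 1.0 / self.spectral_bandwidth


class PatternConfig(BaseModel):
    nominal_R: int = 2
    n_full_inner: int = 5


class GrappaConfig(BaseModel):
    kernel_points: int = 3
    kernel_rings: int = 2
    segment_points: int = 15
    segment_rings: int = 4
    n_time_points: int = 21
    lam: float = 0.0
    recursive: bool = True


class CalibrationConfig(BaseModel):
    mode: Literal["imusical", "static", "moved"] = "imusical"
    n_spec: int = 27
    rotation_deg: Optional[float] = None  # None -> per-mode default
    flip_scale: Optional[float] = None  # None -> per-mode default

    def resolved_rotation(self, mode: str | None = None) -> float:
        m = mode or self.mode
        return DEFAULT_ROTATIONS[m] if self.rotation_deg is None else self.rotation_deg

    def resolved_flip_scale(self, mode: str | None = None) -> float:
        m = mode or self.mode
        return FLIP_SCALES[m] if self.flip_scale is None else self.flip_scale


class EvaluationConfig(BaseModel):
    n_replicas: int = 50
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "tnaa": (1.9, 2.1),
            "tcr": (2.9, 3.1),
            "tcho": (3.1, 3.3),
        }
    )


class RunConfig(BaseModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    pattern: PatternConfig = Field(default_factory=PatternConfig)
    grappa: GrappaConfig = Field(default_factory=GrappaConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.geometry.n_rings > self.geometry.matrix_size // 2:
            raise ValueError("n_rings exceeds the Nyquist limit matrix_size/2")
        if self.grappa.n_time_points > self.calibration.n_spec:
            raise ValueError(
                "grappa.n_time_points exceeds calibration.n_spec"
            )
        return self


PRESETS: dict[str, dict] = {
    "desk": {},
    "full": {
        "geometry": {
            "matrix_size": 64,
            "n_rings": 32,
            "points_per_ring": 540,
            "n_coils": 32,
            "n_spec": 882,
        },
    },
    "tiny": {
        "geometry": {
            "matrix_size": 16,
            "n_rings": 8,
            "points_per_ring": 48,
            "n_coils": 4,
            "n_spec": 32,
        },
        "pattern": {"nominal_R": 2, "n_full_inner": 2},
        "grappa": {"segment_points": 9, "n_time_points": 8},
        "calibration": {"n_spec": 12},
        "evaluation": {"n_replicas": 12},
    },
}


def preset(name: str, **overrides) -> RunConfig:
    """Build a named preset configuration, optionally overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    base = PRESETS[name].copy()
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key] = {**base[key], **val}
        else:
            base[key] = val
    return RunConfig.model_validate(base)
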