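"""Run configuration: a single validated TOML file drives the pipeline.

Every physical parameter carries its unit in the key name.  Unknown
keys are rejected, cross-field constraints (band vs. Nyquist, pulse
vs. period) are enforced before any computation, and the resolved
configuration is written alongside the outputs of every run.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError
from .signal import PulsedSignalSpec, expected_component_count

__all__ = [
    "SignalSection",
    "CoilSection",
    "LesionSection",
    "EvolveSection",
    "PhantomSection",
    "SolverSection",
    "AnalysisSection",
    "RunConfig",
    "validate_config",
    "default_config",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SignalSection(_Section):
    peak_current_A: float = 240.0
    active_phase_ms: float = 1.3
    repetition_hz: float = 75.0
    waveform: str = "trapezoid"
    rise_fraction: float = 0.10
    f_min_hz: float = 75.0
    f_max_hz: float = 7500.0
    f_step_hz: float = 75.0
    n_samples: int = 4096

    @model_validator(mode="after")
    def _check(self):
        # Delegates pulse-level checks (peak >= 0, pulse fits in period).
        self.to_spec()
        expected_component_count(self.f_min_hz, self.f_max_hz, self.f_step_hz)
        nyquist = self.n_samples * self.repetition_hz / 2.0
        if self.f_max_hz > nyquist:
            raise ValueError(
                f"f_max_hz {self.f_max_hz} exceeds the Nyquist limit "
                f"{nyquist} Hz of {self.n_samples} samples per period"
            )
        return self

    def to_spec(self) -> PulsedSignalSpec:
        return PulsedSignalSpec(
            peak_current=self.peak_current_A,
            active_phase=self.active_phase_ms * 1e-3,
            repetition_frequency=self.repetition_hz,
            waveform_shape=self.waveform,
            rise_fraction=self.rise_fraction,
        )

    @property
    def band(self):
        return (self.f_min_hz, self.f_max_hz, self.f_step_hz)


class CoilSection(_Section):
    width_m: float = Field(0.14, gt=0)
    height_m: float = Field(0.106, gt=0)
    standoff_mm: float = Field(5.0, ge=0)
    direction: Sequence[float] = (1.0, 0.0, 0.1)
    auto_center_on_lesion: bool = True
    segments_per_side: int = Field(1, ge=1)


class LesionSection(_Section):
    centroid_mm: Sequence[float] = (28.0, 0.0, 5.0)
    radii_mm: Sequence[float] = (24.0, 20.0, 20.0)
    irregularity: float = Field(0.25, ge=0)
    seed: int = 11

    @model_validator(mode="after")
    def _check(self):
        if len(self.centroid_mm) != 3 or len(self.radii_mm) != 3:
            raise ValueError("centroid_mm and radii_mm must have 3 entries")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be positive")
        return self


class EvolveSection(_Section):
    m_true: float = Field(79.38, gt=0)
    a_true: float = -0.1
    exposure_floor_mT: float = Field(0.5, ge=0)
    growth_rate_untreated: float = Field(0.3, ge=0)
    apply_closing: bool = False
    seed: int = 101


class PhantomSection(_Section):
    radius_mm: float = Field(80.0, gt=0)
    voxel_mm: float = Field(2.0, gt=0)
    skin_mm: float = Field(4.0, ge=0)
    skull_mm: float = Field(7.0, ge=0)
    csf_mm: float = Field(3.0, ge=0)
    grey_mm: float = Field(15.0, ge=0)
    tissue_table_csv: Optional[str] = None
    mri_noise_sd: float = Field(4.0, ge=0)
    mri_slice_mm: float = Field(4.0, gt=0)
    mri_seed: int = 7
    lesion: LesionSection = LesionSection()
    evolve: EvolveSection = EvolveSection()

    @model_validator(mode="after")
    def _check(self):
        total = self.skin_mm + self.skull_mm + self.csf_mm + self.grey_mm
        if total >= self.radius_mm:
            raise ValueError("layer thicknesses must sum to less than the radius")
        return self

    @property
    def layers(self):
        return (("skin", self.skin_mm), ("skull", self.skull_mm),
                ("csf", self.csf_mm), ("grey", self.grey_mm))


class SolverSection(_Section):
    tolerance: float = Field(1e-9, gt=0, lt=1)
    max_iterations: int = Field(30_000, ge=1)
    include_displacement: bool = True
    fast_mode: bool = False
    n_harmonics: int = Field(12, ge=1)


class AnalysisSection(_Section):
    b_edges_mT: Sequence[float] = (1.0, 1.3, 1.7, 2.0)
    j_edges_mA_m2: Sequence[float] = (5.0, 10.0, 20.0, 50.0)
    threshold_step_mT: float = Field(0.1, gt=0)
    bin_width_mT: float = Field(0.05, gt=0)
    slice_spacing_mm: float = Field(5.0, gt=0)
    slice_plane: str = "d"

    @model_validator(mode="after")
    def _check(self):
        for name in ("b_edges_mT", "j_edges_mA_m2"):
            edges = list(getattr(self, name))
            if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} must be strictly increasing, >= 2 entries")
        if self.slice_plane not in ("d", "f", "t"):
            raise ValueError("slice_plane must be one of d/f/t")
        return self


class RunConfig(_Section):
    signal: SignalSection = SignalSection()
    coil: CoilSection = CoilSection()
    phantom: PhantomSection = PhantomSection()
    solver: SolverSection = SolverSection()
    analysis: AnalysisSection = AnalysisSection()
    output_dir: str = "runs"
    log_level: str = "INFO"


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def validate_config(path) -> RunConfig:
    """Load and fully validate a TOML run configuration.

    All errors are aggregated into one human-readable message.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"config file {path} is not valid TOML: {exc}")
    return validate_mapping(raw, source=str(path))


def validate_mapping(raw: dict, source: str = "<dict>") -> RunConfig:
    """Validate an already-parsed configuration mapping."""
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(
            f"invalid configuration ({source}):\n{_format_errors(exc)}"
        ) from exc


def default_config() -> RunConfig:
    return RunConfig()
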