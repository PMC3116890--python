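"""Run configuration: validated YAML in, dataclass parameter records out.

A run configuration bundles the stimulation protocol, the coupling model
choice, noise/seed settings and optimizer policy.  Unknown keys are
rejected, omitted fields fall back to the documented defaults (prior-mean
parameters, 7-frequency protocol), and cross-field invariants (every
frequency has a luminance factor, a seed accompanies noise) are enforced
at load time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .coupling import MODEL_IDS
from .inversion import VLSettings
from .stimulus import DEFAULT_LUMINANCE, StimulusProtocol

__all__ = ["RunConfig", "load_config", "save_config"]


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    frequencies: list[float] = Field(
        default_factory=lambda: [4.0, 7.5, 10.0, 12.0, 15.0, 20.0, 30.0])
    stim_s: float = 15.3
    rest_s: float = 15.3
    tr_s: float = 3.06
    pulse_width_s: float = 1.0 / 60.0
    delay_s: float = 0.1
    amplitude: float = 3.0
    luminance: dict[float, float] = Field(
        default_factory=lambda: dict(DEFAULT_LUMINANCE))

    def to_protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            frequencies=tuple(self.frequencies),
            stim_duration=self.stim_s,
            rest_duration=self.rest_s,
            tr=self.tr_s,
            pulse_width=self.pulse_width_s,
            delay=self.delay_s,
            amplitude=self.amplitude,
            luminance_factors=dict(self.luminance),
        )


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    snr_eeg: float = 1.0
    snr_bold: float = 2.0
    seed: int | None = 0


class VLConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_iter: int = 32
    f_tol: float = 0.01
    noise_mode: str = "estimated"
    sigma0: float = 1.0

    def to_settings(self) -> VLSettings:
        return VLSettings(max_iter=self.max_iter, f_tol=self.f_tol,
                          noise_mode=self.noise_mode, sigma0=self.sigma0)


class RunConfig(BaseModel):
    """Validated run configuration with defaults for every omitted field."""

    model_config = ConfigDict(extra="forbid")

    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    coupling: str = "in"
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    vl: VLConfig = Field(default_factory=VLConfig)
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.coupling not in MODEL_IDS:
            raise ValueError(
                f"coupling must be one of {MODEL_IDS}, got {self.coupling!r}")
        missing = [f for f in self.protocol.frequencies
                   if f not in self.protocol.luminance]
        if missing:
            raise ValueError(
                f"frequencies {missing} missing from the luminance table")
        if (self.noise.snr_eeg or self.noise.snr_bold) and \
                self.noise.seed is None:
            raise ValueError("a seed is required whenever noise is enabled")
        # raises on invariant violations (sorted, positive, ...)
        self.protocol.to_protocol()
        return self

    def digest(self) -> str:
        """Stable content hash for provenance records."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full-default configuration.  Unknown keys,
    missing luminance entries and invariant violations raise ``ValueError``
    with the offending field named.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise ValueError(f"{path}: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False))
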