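"""Pipeline configuration: every numeric default is the analysis constant
used throughout (mask threshold 2.0x occipital, cluster-defining p 0.001,
cluster FWE alpha 0.05, framewise-displacement cut-off 0.5 mm, putaminal
z cut-off -2.5, band-pass 0.01-0.08 Hz, smoothing FWHM 5 mm, seed radius
5 mm).  Configurations round-trip losslessly through YAML, and all
randomness in a run flows from the single root seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # thresholds
    mask_threshold: float = 2.0        # cohort-mean local SBR cut-off
    cdt_p: float = 0.001               # cluster-defining uncorrected p
    alpha: float = 0.05                # cluster-level FWE
    fd_max: float = 0.5                # mm, frame scrubbing
    z_cutoff: float = -2.5             # putaminal z for DaT+/-
    # band-pass (Hz)
    bandpass_low: float = 0.01
    bandpass_high: float = 0.08
    # spatial
    smoothing_fwhm: float = 5.0        # mm
    seed_radius: float = 5.0           # mm
    # inference
    n_perm: int = 5000
    seed: int = 0
    # behaviour
    pi_variant: str = "shifted_exp"
    # paths
    input_dir: str = ""
    output_dir: str = ""

    def __post_init__(self) -> None:
        if self.bandpass_high <= self.bandpass_low:
            raise ValueError("bandpass_high must exceed bandpass_low")
        if not 0 < self.cdt_p < 1 or not 0 < self.alpha < 1:
            raise ValueError("cdt_p and alpha must lie in (0, 1)")
        if self.pi_variant not in ("shifted_exp", "expm1"):
            raise ValueError(f"unknown pi_variant {self.pi_variant!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration, stamped into provenance logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
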