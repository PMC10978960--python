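"""Run configuration: all tunable thresholds in one place.

A plain-text ``key = value`` file can override the defaults; CLI flags
override the file.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

_POSITIVE_FIELDS = (
    "gate_in_threshold", "gate_out_threshold", "hbond_cutoff",
    "homolog_identity_pct", "homolog_coverage_pct", "noise_floor_pct",
    "flip_threshold_deg", "domain_angle_tol_deg", "open_anchor_deg",
    "cation_cutoff",
)


@dataclass
class RunConfig:
    """Threshold set and run options (distances in Angstrom, angles in
    degrees, percentages in percent)."""

    gate_in_threshold: float = 6.0
    gate_out_threshold: float = 8.0
    hbond_cutoff: float = 3.5
    cation_cutoff: float = 6.0
    homolog_identity_pct: float = 30.0
    homolog_coverage_pct: float = 70.0
    noise_floor_pct: float = 1.0
    flip_threshold_deg: float = 120.0
    domain_angle_tol_deg: float = 6.0
    open_anchor_deg: float = 18.0
    reference: str = "pfu"
    output_dir: str = "."
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if self.gate_in_threshold >= self.gate_out_threshold:
            raise ConfigurationError(
                "gate_in_threshold must be below gate_out_threshold"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"no such config file: {path}")
        valid = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            field_type = {f.name: f for f in dataclasses.fields(cls)}[key].type
            try:
                if field_type == "float":
                    kwargs[key] = float(value)
                elif field_type == "int":
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = value
            except ValueError as exc:
                raise ConfigurationError(
                    f"{path}:{lineno}: bad value for {key}: {value!r}"
                ) from exc
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
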