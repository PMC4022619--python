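"""Pipeline configuration: one YAML/JSON file drives every CLI command."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .scenarios import DEFAULT_DISTANCES_M, SPECIES_DISTANCES_M
from .synthetic import SyntheticConfig


@dataclass
class PipelineConfig:
    """Resolved settings for a pipeline run.

    Exactly one input source must be present: either a waterhole layer path
    (with optional boundary/reserve polygons) or a synthetic-landscape
    configuration. ``species`` may name a movement preset (tapir, peccary,
    jaguar) that replaces the distance list.
    """

    waterholes: str | None = None
    boundary: str | None = None
    reserve: str | None = None
    synthetic: SyntheticConfig | None = None
    distances: tuple[float, ...] = DEFAULT_DISTANCES_M
    species: str | None = None
    tail_prob: float = 0.05
    include_self: bool = True
    pair_mode: str = "max_product"
    buffer_radii: tuple[float, ...] = (1_000.0, 2_000.0)
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.waterholes is None and self.synthetic is None:
            raise ConfigurationError(
                "config needs either a 'waterholes' path or a 'synthetic' block"
            )
        if self.species is not None:
            if self.species not in SPECIES_DISTANCES_M:
                raise ConfigurationError(
                    f"unknown species preset {self.species!r}; "
                    f"choose from {sorted(SPECIES_DISTANCES_M)}"
                )
            self.distances = SPECIES_DISTANCES_M[self.species]
        self.distances = tuple(float(d) for d in self.distances)
        self.buffer_radii = tuple(float(r) for r in self.buffer_radii)
        if any(d <= 0 for d in self.distances) or any(r <= 0 for r in self.buffer_radii):
            raise ConfigurationError("distances and buffer radii must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(synthetic=syn, **raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["distances"] = list(self.distances)
        d["buffer_radii"] = list(self.buffer_radii)
        return d

    def scientific_dict(self) -> dict:
        """Resolved config minus run-local keys (out_dir, log_level).

        Two runs with the same scientific settings and seed have the same
        scientific dict, and hence identical manifests, regardless of where
        their outputs land.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return d

    def content_hash(self) -> str:
        """Stable SHA-256 of the scientific configuration."""
        blob = json.dumps(self.scientific_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
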