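"""Run configuration: one structured YAML file, every field CLI-overridable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assay import DEFAULT_FOLD_THRESHOLD
from .imaging import SegmentationParams


@dataclass
class AssayOptions:
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    normalization: str = "percent_highest"


@dataclass
class FitOptions:
    scale: str = "doublings"  # response scale for IC50 fits
    weight_positive: float = 1.0  # bulk-surrogate per-cell signal weights
    weight_negative: float = 1.0


@dataclass
class SimulateOptions:
    scenario: str = "default"
    n_doses: int | None = None
    n_replicates: int | None = None


@dataclass
class RunConfig:
    """Master configuration; the seed is recorded in every output manifest."""

    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    assay: AssayOptions = field(default_factory=AssayOptions)
    fit: FitOptions = field(default_factory=FitOptions)
    simulate: SimulateOptions = field(default_factory=SimulateOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "segmentation": SegmentationParams,
            "assay": AssayOptions,
            "fit": FitOptions,
            "simulate": SimulateOptions,
        }
        unknown = set(raw) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {"seed": int(raw.get("seed", 0))}
        for name, klass in sections.items():
            sub = raw.get(name, {}) or {}
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - valid
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            kwargs[name] = klass(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the full configuration (reproducibility manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
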