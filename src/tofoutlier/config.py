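"""Pipeline configuration: one master seed, per-stage parameter blocks.

A single master seed deterministically derives every stage seed, so the
whole simulate -> extract -> train -> evaluate pipeline is reproducible
from one knob.  Configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluate import ExperimentConfig, SplitSpec
from .features import FeatureParams
from .synth import GeneratorConfig


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed from (master seed, stage name); stable across platforms."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    extraction: FeatureParams = field(default_factory=FeatureParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    master_seed: int = 42
    output_dir: str = "tofoutlier_out"
    log_level: str = "INFO"

    def with_derived_seeds(self) -> "PipelineConfig":
        """Copy with every stage seed derived from the master seed."""
        gen = self.generator.replace(seed=derive_seed(self.master_seed, "simulate"))
        split = dataclasses.replace(
            self.experiment.split, seed=derive_seed(self.master_seed, "split")
        )
        exp = dataclasses.replace(
            self.experiment, split=split, seed=derive_seed(self.master_seed, "eval")
        )
        return dataclasses.replace(self, generator=gen, experiment=exp)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig(**_tuplify(GeneratorConfig, d["generator"]))
        if "extraction" in d:
            d["extraction"] = FeatureParams(**d["extraction"])
        if "experiment" in d:
            e = dict(d["experiment"])
            if "split" in e:
                e["split"] = SplitSpec(**e["split"])
            if "grid" in e and e["grid"] is not None:
                e["grid"] = [tuple(g) for g in e["grid"]]
            if "learning_curve_sizes" in e:
                e["learning_curve_sizes"] = tuple(e["learning_curve_sizes"])
            d["experiment"] = ExperimentConfig(**e)
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})


def _tuplify(cls, d: dict) -> dict:
    """Coerce YAML lists back to tuples where the dataclass expects them."""
    out = dict(d)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list) and "tuple" in str(f.type):
            out[f.name] = tuple(out[f.name])
    return out


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
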