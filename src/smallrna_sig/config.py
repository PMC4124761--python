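"""Single YAML-backed configuration for the whole pipeline.

Every threshold the method leaves open is surfaced here with its default:
adapter-trimming tolerances, the clean-read quality rule, the annotation
overlap fraction and strand rule, the RPM denominator, the fold-change
zero-guard, bin sizes and the endo-siRNA screen bounds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class PreprocessConfig:
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = ""
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_len: int = 18
    max_len: int = 40  # gel size-selection window
    min_mean_quality: float = 20.0
    discard_adapter5: bool = False
    contaminants: list[str] = field(default_factory=list)


@dataclass
class AnnotateConfig:
    min_overlap_frac: float = 0.8
    pirna_strand_agnostic: bool = False


@dataclass
class MirnaConfig:
    #: 'mirna_total' normalizes to miRNA-annotated reads; 'genome_mapped'
    #: to all mapped reads
    rpm_denominator: str = "mirna_total"
    expressed_rpm: float = 1.0
    focal_sample: str = "SSC"
    fold: float = 2.0
    epsilon: float = 0.5
    vs: str = "each"
    cluster_pseudocount: float = 1.0


@dataclass
class PirnaConfig:
    bin_size: int = 1000  # 100 kb is the sensible default on a real genome
    #: samples whose weighted piRNA total falls below this fraction of the
    #: best sample are left out of distribution plots
    plot_floor_fraction: float = 0.02
    enrichment_alpha: float = 0.05


@dataclass
class SirnaConfig:
    min_len: int = 18
    max_len: int = 23
    repeat_overlap_frac: float = 0.5


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    mirna: MirnaConfig = field(default_factory=MirnaConfig)
    pirna: PirnaConfig = field(default_factory=PirnaConfig)
    sirna: SirnaConfig = field(default_factory=SirnaConfig)
    #: sample ordering used for developmental trend labels
    sample_order: list[str] = field(default_factory=lambda: ["ESC", "SSC", "GC"])
    index_k: int = 18
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in fields(cls)}
        for key, value in data.items():
            if key not in sections:
                raise ValueError(f"unknown config section or key: {key!r}")
            current = getattr(cfg, key)
            if isinstance(value, Mapping):
                valid = {f.name for f in fields(current)}
                unknown = set(value) - valid
                if unknown:
                    raise ValueError(
                        f"unknown keys in config section {key!r}: {sorted(unknown)}"
                    )
                for k, v in value.items():
                    setattr(current, k, v)
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.mirna.rpm_denominator not in ("mirna_total", "genome_mapped"):
            raise ValueError("mirna.rpm_denominator must be 'mirna_total' or 'genome_mapped'")
        if self.mirna.vs not in ("each", "mean"):
            raise ValueError("mirna.vs must be 'each' or 'mean'")
        if self.preprocess.min_len > self.preprocess.max_len:
            raise ValueError("preprocess.min_len must not exceed max_len")
        if not 0 < self.annotate.min_overlap_frac <= 1:
            raise ValueError("annotate.min_overlap_frac must lie in (0, 1]")
        if self.sirna.min_len > self.sirna.max_len:
            raise ValueError("sirna.min_len must not exceed max_len")
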