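"""Run configuration: every tunable of the pipeline with validated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

from .refset import ValidationError


@dataclass
class RunConfig:
    """All pipeline parameters in one place.

    Defaults are the method's published constants: MAPQ cut 20, switch
    penalty 0.0028, top-5% candidate shortlist, minimum per-haplotype depth
    30 for ratio reporting, annotation restricted to protein-coding
    transcripts of level <= 2.
    """

    min_mapq: int = 20
    score_function: str = "exp2"  # "exp2" | "inverse"
    pair_rate: str = "count"  # "count" | "weight-sum"
    top_percentile: float = 95.0
    penalty: float = 0.0028
    epsilon: float = 1e-9
    min_depth: float = 30.0
    unique_scope: str = "pair"  # "pair" | "global"
    stranded: bool = False
    md_fallback: bool = False
    gene_types: tuple[str, ...] = ("protein_coding",)
    max_level: int = 2
    min_unique_fraction: float = 0.8
    max_mismap_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 255:
            raise ValidationError("min_mapq outside [0, 255]")
        if self.score_function not in {"exp2", "inverse"}:
            raise ValidationError(f"unknown score_function {self.score_function!r}")
        if self.pair_rate not in {"count", "weight-sum"}:
            raise ValidationError(f"unknown pair_rate {self.pair_rate!r}")
        if not 0 < self.top_percentile <= 100:
            raise ValidationError("top_percentile outside (0, 100]")
        if self.penalty < 0:
            raise ValidationError("penalty must be >= 0")
        if not 0 < self.epsilon < 0.5:
            raise ValidationError("epsilon outside (0, 0.5)")
        if self.min_depth < 0:
            raise ValidationError("min_depth must be >= 0")
        if self.unique_scope not in {"pair", "global"}:
            raise ValidationError(f"unknown unique_scope {self.unique_scope!r}")
        if self.max_level < 1:
            raise ValidationError("max_level must be >= 1")
        for frac in (self.min_unique_fraction, self.max_mismap_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("filter fractions must be in [0, 1]")
        if isinstance(self.gene_types, list):
            self.gene_types = tuple(self.gene_types)

    @classmethod
    def from_file(cls, path: str, **overrides: Any) -> "RunConfig":
        """Load YAML or JSON config; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValidationError(f"config {path} is not a mapping")
        data = dict(data)
        data.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_types"] = list(d["gene_types"])
        return d
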