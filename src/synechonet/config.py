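"""Pipeline configuration with validation and YAML loading."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    compendium: str
    annotations: str
    membership: str
    outdir: str
    scenarios: str | None = None
    upstream_fasta: str | None = None
    alpha: float = 0.05
    min_replicates: int = 3
    ctr_threshold: float = 0.5
    ctr_strict: bool = True
    coregulation_cutoff: float = 0.6
    min_genes: int = 3
    min_frac: float = 0.10
    max_parents: int = 4
    pseudocount: float = 1.0
    seed: int = 0
    scale_strategy: str = "fitted"
    pooling: str = "means"
    link_strength_mode: str = "marginal"

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.min_replicates >= 1, "min_replicates must be >= 1"),
            (0 <= self.ctr_threshold <= 1, "ctr_threshold must be in [0, 1]"),
            (0 <= self.coregulation_cutoff <= 1, "coregulation_cutoff must be in [0, 1]"),
            (self.min_genes >= 1, "min_genes must be >= 1"),
            (0 <= self.min_frac <= 1, "min_frac must be in [0, 1]"),
            (self.max_parents >= 1, "max_parents must be >= 1"),
            (self.pseudocount >= 0, "pseudocount must be non-negative"),
            (self.scale_strategy in ("fitted", "pooled"), "scale_strategy invalid"),
            (self.pooling in ("means", "raw"), "pooling invalid"),
            (self.link_strength_mode in ("marginal", "conditional"), "link_strength_mode invalid"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**doc)
        cfg.validate()
        return cfg
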