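"""Run configuration: one YAML file carrying every threshold of the pipeline.

Defaults are the study's printed values: locus coordinates, z decision lines
(+/-0.1 low, +/-0.3 high/deep), droplet gates (6,000 / 10,000 / 5,500 /
7,000), absolute-CN lines (2.3 / 1.7), the RNA-seq filter cutoffs (500 bp,
25th percentile, median) and the fold-change cutoff of 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cna import CnaThresholds
from .ddpcr import DEFAULT_TP53_NORMAL_RANGE, GateConfig


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    # input paths (optional; the simulate subcommand writes them)
    segments: str | None = None
    mutations: str | None = None
    expression: str | None = None
    clinical: str | None = None
    droplets: list[str] = field(default_factory=list)
    counts: str | None = None
    gene_lengths: str | None = None
    gene_sets: str | None = None
    ranked_list: str | None = None
    # thresholds
    low_gain: float = 0.1
    high_gain: float = 0.3
    low_loss: float = -0.1
    deep_loss: float = -0.3
    amp_threshold: float = 2.3
    loss_threshold: float = 1.7
    wt_gate: float = 6000.0
    mut_gate: float = 10000.0
    tp53_gate: float = 5500.0
    tert_gate: float = 7000.0
    tp53_normal_low: float = DEFAULT_TP53_NORMAL_RANGE[0]
    tp53_normal_high: float = DEFAULT_TP53_NORMAL_RANGE[1]
    min_gene_length: int = 500
    density_quantile: float = 0.25
    fc_cutoff: float = 2.0
    alpha_q: float = 0.05
    instability_threshold: float = 0.1
    n_perm: int = 1000

    def cna_thresholds(self) -> CnaThresholds:
        return CnaThresholds(self.low_gain, self.high_gain, self.low_loss, self.deep_loss)

    def gates(self) -> GateConfig:
        return GateConfig(self.wt_gate, self.mut_gate, self.tp53_gate, self.tert_gate)

    def tp53_range(self) -> tuple[float, float]:
        if not self.tp53_normal_low < self.tp53_normal_high:
            raise ValueError("tp53 normal range must be increasing")
        return (self.tp53_normal_low, self.tp53_normal_high)

    def validate(self) -> "RunConfig":
        self.cna_thresholds()
        self.gates()
        self.tp53_range()
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if not 0 < self.density_quantile < 1:
            raise ValueError("density_quantile must lie in (0, 1)")
        if not 0 < self.alpha_q <= 1:
            raise ValueError("alpha_q must lie in (0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
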