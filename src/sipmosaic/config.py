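"""Run configuration: one YAML file drives every pipeline stage.

Unknown keys are rejected so that a typo in a threshold name fails loudly
instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    # paths
    out_dir: str = "results"
    reads_fasta: str | None = None
    references_fasta: str | None = None
    annotations_tsv: str | None = None
    primers_tsv: str | None = None
    plate_csv: str | None = None
    query_label: str | None = None
    parent_a_label: str | None = None
    parent_b_label: str | None = None

    # simulation
    seed: int = 0
    n_reads: int = 10_000
    read_min_len: int = 30
    read_max_len: int = 530
    sub_rate: float = 0.005
    indel_rate: float = 0.001
    mixture_weights: list[float] = field(default_factory=lambda: [0.643, 0.177, 0.180])
    parent_divergence: float = 0.1
    novel_rate: float = 0.005
    leakage: float = 0.05
    sip_n_reads: int = 3000

    # attribution
    call_margin: float = 2.0
    min_run: int = 3
    novel_threshold: float = 5.0

    # quantification
    recruit_min_identity: float = 0.80
    assign_margin: float = 0.005
    min_overlap: int = 20

    # 16S / enrichment
    min_identity_16s: float = 0.97
    pseudocount: float = 0.5
    min_ratio: float = 5.0
    min_heavy_abundance: float = 1.0

    # PCR
    max_mismatch: int = 0
    max_product_len: int = 10_000
    min_hit_reads: int = 5

    # kinetics
    fold_threshold: float = 2.0

    def validate(self) -> None:
        checks = [
            (0.0 <= self.recruit_min_identity <= 1.0, "recruit_min_identity in [0,1]"),
            (0.0 <= self.assign_margin <= 1.0, "assign_margin in [0,1]"),
            (0.0 <= self.min_identity_16s <= 1.0, "min_identity_16s in [0,1]"),
            (self.pseudocount > 0, "pseudocount > 0"),
            (self.min_ratio > 0, "min_ratio > 0"),
            (0 <= self.novel_rate < 0.2, "novel_rate in [0,0.2)"),
            (0 <= self.leakage < 0.5, "leakage in [0,0.5)"),
            (30 <= self.read_min_len <= self.read_max_len, "30 <= read_min_len <= read_max_len"),
            (self.max_mismatch >= 0, "max_mismatch >= 0"),
            (self.fold_threshold > 0, "fold_threshold > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config: {msg}")


def load_config(path: str | None) -> RunConfig:
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for k, v in data.items():
            setattr(cfg, k, v)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
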