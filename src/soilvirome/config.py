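"""Pipeline configuration: thresholds, paths, seeds.

Threshold defaults are the study's operating points: retention at 5 kbp /
50% completeness, vOTU clustering at 95% ANI / 85% AF, a 10% breadth mask
for RPKM, 50% coding-strand breadth for expressed genes and ssRNA
detection, branch-support collapse below 50, effect size > 0.3 with
Storey q ≤ 0.05 for seasonal calls, and generalized UniFrac α = 0.5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    out_dir: str = "soilvirome_run"
    # inputs (populated by `simulate` or pointing at real data)
    genomes: str = ""
    genes: str = ""
    categories: str = ""
    placements: str = ""
    libraries: str = ""
    tree: str = ""
    tree_annotations: str = ""
    host_strategies: str = ""
    # thresholds
    min_len: int = 5000
    min_completeness: float = 50.0
    ani: float = 95.0
    af: float = 85.0
    breadth_mask: float = 10.0
    gene_breadth: float = 50.0
    rna_breadth: float = 50.0
    support_collapse: float = 50.0
    effect_min: float = 0.3
    q_max: float = 0.05
    unifrac_alpha: float = 0.5
    n_permutations: int = 999
    stranded_protocol: str = "rf"
    # synthetic community
    seed: int = 0
    n_votus: int = 60
    length_min: int = 5000
    length_max: int = 15000
    molecule_mix: float = 0.2
    gene_density: float = 1.0
    seasonal_fraction: float = 0.05
    active_fraction: float = 0.5
    depth_per_active_gene: float = 20.0
    noise_dispersion: float = 5.0
    neg_strand_fraction: float = 0.2
    noiseless: bool = False
    months: list[str] = field(default_factory=lambda: ["Mar", "May", "Jun", "Sep"])
    depths: list[str] = field(default_factory=lambda: ["00-05cm", "05-15cm", "15cm-plus"])
    locations: list[str] = field(default_factory=lambda: ["upslope", "downslope"])
    replicates_per_cell: int = 2
    library_size_mean: int = 100_000

    def __post_init__(self) -> None:
        for name in ("min_completeness", "ani", "af", "breadth_mask", "gene_breadth",
                     "rna_breadth", "support_collapse"):
            value = getattr(self, name)
            if not (0 <= value <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {value}")
        if not (0 <= self.effect_min <= 1) or not (0 <= self.q_max <= 1):
            raise ValueError("effect_min and q_max must be in [0, 1]")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
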