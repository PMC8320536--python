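"""Configuration blocks for every pipeline stage, loadable from one YAML file.

Defaults are the thresholds used for the liver-cancer analysis the method
was developed on; ``kirc_profile()`` returns the published alternative used
for kidney renal clear cell carcinoma (Diff-MN degree > 10).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    #: genes must be expressed in strictly more than this fraction of samples
    min_expressed_fraction: float = 0.5
    #: a value strictly above this counts as "expressed" in a sample
    expression_presence_threshold: float = 0.0
    #: PPI edges need a combined score strictly greater than this
    ppi_min_confidence: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.min_expressed_fraction <= 1:
            raise ValueError("min_expressed_fraction must be in [0, 1]")
        if not 1 <= self.ppi_min_confidence <= 999:
            raise ValueError("ppi_min_confidence must be in [1, 999]")


@dataclass
class SignificanceConfig:
    #: BH-adjusted two-sided Pearson p threshold for the correlation network
    pearson_alpha: float = 0.01
    #: Bonferroni-adjusted p threshold for the partial-correlation network
    partial_alpha: float = 0.05
    #: condition on all other genes instead of network common neighbors
    exhaustive_conditioning: bool = False

    def __post_init__(self) -> None:
        for v in (self.pearson_alpha, self.partial_alpha):
            if not 0 < v < 1:
                raise ValueError("alphas must be in (0, 1)")


@dataclass
class DiffNetworkConfig:
    #: differential methylation score must be strictly greater than this
    meth_score_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.meth_score_threshold <= 2:
            raise ValueError("meth_score_threshold must be in [0, 2]")


@dataclass
class RankingConfig:
    diff_pcorn_min_degree: int = 30
    diff_mn_min_degree: int = 15
    top_k: int = 15

    def __post_init__(self) -> None:
        if min(self.diff_pcorn_min_degree, self.diff_mn_min_degree, self.top_k) <= 0:
            raise ValueError("ranking thresholds must be positive")


@dataclass
class SyntheticConfig:
    """Conditions for the paired synthetic multi-omics dataset (see simulate)."""

    n_genes: int = 200
    n_tumor: int = 120
    n_normal: int = 40
    #: average degree of the PPI scaffold (decoy edges fill up to this)
    background_degree: float = 4.0
    n_disease_genes: int = 10
    #: tumor-only direct edges planted per disease gene
    disease_edges_per_gene: int = 12
    #: partial correlation of planted disease (tumor-only) direct edges
    direct_edge_strength: float = 0.25
    #: partial correlation of chain edges i-k and k-j
    chain_edge_strength: float = 0.6
    #: i-k-j chains planted with no direct i-j edge
    n_indirect_chains: int = 20
    #: both-group direct edges among non-disease genes
    n_shared_edges: int = 40
    shared_edge_strength: float = 0.2
    #: methylation sites per gene, inclusive range
    sites_per_gene: tuple[int, int] = (1, 3)
    #: target |r_tumor - r_normal| on disease-edge site pairs
    diff_meth_effect: float = 0.8
    disease_mutation_rate: float = 0.4
    background_mutation_rate: float = 0.05
    #: latent-SD expression shift of disease genes in tumor samples
    disease_expression_shift: float = 1.2
    #: exponentiate latent Gaussians to an FPKM-like non-negative scale
    fpkm_transform: bool = True
    #: log-scale SD of the FPKM-like transform (per-gene latents are
    #: standardised, then exp(mu_g + fpkm_log_sd * z) is taken)
    fpkm_log_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.disease_mutation_rate, self.background_mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("mutation rates must be in [0, 1]")
        if isinstance(self.sites_per_gene, list):
            self.sites_per_gene = tuple(self.sites_per_gene)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    diff_network: DiffNetworkConfig = field(default_factory=DiffNetworkConfig)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    #: input paths (unused when running on a simulated dataset)
    expression_path: str | None = None
    label_path: str | None = None
    methylation_path: str | None = None
    methylation_annotation_path: str | None = None
    mutation_path: str | None = None
    ppi_path: str | None = None
    reference_gene_lists: dict[str, str] = field(default_factory=dict)
    barcode_prefix_len: int | None = None
    out_dir: str = "dpcnet_out"
    seed: int = 0


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "significance": SignificanceConfig,
    "diff_network": DiffNetworkConfig,
    "ranking": RankingConfig,
    "synthetic": SyntheticConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](**(val or {}))
        else:
            kwargs[key] = val
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(kwargs) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def kirc_profile() -> RankingConfig:
    """Degree thresholds used for the kidney (KIRC) replication."""
    return RankingConfig(diff_pcorn_min_degree=30, diff_mn_min_degree=10, top_k=15)
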