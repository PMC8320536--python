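"""Seeded generator of paired expression / methylation / mutation datasets
with known ground truth.

Expression is drawn per group from a zero-mean Gaussian graphical model
whose precision matrix has unit diagonal and ``-strength`` on planted
edges, so the planted (full-order) partial correlation of every direct edge
equals its configured strength exactly; positive definiteness is verified
and a non-PD configuration raises, naming the offending strength.  The
planted structure:

* each disease gene gains ``disease_edges_per_gene`` tumor-only direct
  edges (a hub whose near-singular star inflates marginal correlations,
  making the edges detectable at realistic sample sizes);
* ``n_indirect_chains`` chains i–k–j exist in both groups with no direct
  i–j edge — the i–j pairs correlate marginally but are conditionally
  independent given k, the exact confound first-order partial correlation
  is meant to remove;
* ``n_shared_edges`` weak direct edges are common to both groups;
* the PPI scaffold is the union of all planted edges, the chain-endpoint
  pairs, and random decoy edges up to ``background_degree``.

Latent Gaussians are exponentiated to an FPKM-like non-negative scale (a
monotone transform that mildly attenuates Pearson correlations — a
deliberate stressor, disabled via ``fpkm_transform=False``).  Disease genes
additionally get a positive latent mean shift in tumor samples.

Methylation Beta values are logistic squashes of correlated Gaussians: in
tumor samples the CpG sites of a disease gene and of its partners share a
per-disease-gene latent factor (site–site correlation ~ ``diff_meth_effect``),
absent in normal samples, so planted disease edges carry a large
differential co-methylation score.  Mutations are per-gene per-tumor-sample
Bernoulli indicators with an elevated rate for disease genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import (
    DiffNetworkConfig,
    PreprocessConfig,
    RankingConfig,
    SignificanceConfig,
    SyntheticConfig,
)
from .datatypes import (
    DataError,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    OmicsDataset,
    SampleGroups,
    canonical_edge,
)

log = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    disease_genes: set[str]
    direct_edges_tumor: set[Edge]
    direct_edges_normal: set[Edge]
    indirect_pairs: set[Edge]
    differential_meth_edges: set[Edge]

    def to_dict(self) -> dict:
        return {
            "disease_genes": sorted(self.disease_genes),
            "direct_edges_tumor": sorted(map(list, self.direct_edges_tumor)),
            "direct_edges_normal": sorted(map(list, self.direct_edges_normal)),
            "indirect_pairs": sorted(map(list, self.indirect_pairs)),
            "differential_meth_edges": sorted(map(list, self.differential_meth_edges)),
        }


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _precision_matrix(
    n: int, genes: list[str], edges: dict[Edge, float]
) -> np.ndarray:
    idx = {g: i for i, g in enumerate(genes)}
    omega = np.eye(n)
    for (a, b), s in edges.items():
        omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = -s
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        worst = max(edges.items(), key=lambda kv: abs(kv[1]))
        raise DataError(
            "planted precision matrix is not positive definite; "
            f"reduce edge strengths (largest: {worst[0]} at {worst[1]})"
        ) from None
    return omega


def _sample_group(
    omega: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw genes x samples latent Gaussians with covariance inv(omega)."""
    cov = np.linalg.inv(omega)
    # symmetrise against round-off before Cholesky
    cov = (cov + cov.T) / 2.0
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    z = rng.standard_normal((omega.shape[0], n_samples))
    return L @ z


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(config: SyntheticConfig | None = None) -> tuple[OmicsDataset, GroundTruth]:
    """Generate one paired multi-omics dataset plus its ground truth."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)

    n_chain_genes = 3 * cfg.n_indirect_chains
    needed = n_chain_genes + cfg.n_disease_genes
    if needed > cfg.n_genes:
        raise DataError(
            f"config needs at least {needed} genes for chains and disease genes"
        )
    perm = [str(g) for g in rng.permutation(genes)]
    chain_genes = perm[:n_chain_genes]
    disease_genes = sorted(perm[n_chain_genes:needed])
    pool = sorted(perm[needed:])  # partners, shared edges, decoys

    # --- planted edge sets -------------------------------------------------
    chain_edges: dict[Edge, float] = {}
    indirect_pairs: set[Edge] = set()
    for c in range(cfg.n_indirect_chains):
        i, k, j = chain_genes[3 * c : 3 * c + 3]
        if cfg.chain_edge_strength:
            chain_edges[canonical_edge(i, k)] = cfg.chain_edge_strength
            chain_edges[canonical_edge(k, j)] = cfg.chain_edge_strength
        indirect_pairs.add(canonical_edge(i, j))

    n_partners = cfg.n_disease_genes * cfg.disease_edges_per_gene
    if n_partners > len(pool):
        raise DataError(
            f"config needs {n_partners} partner genes but only {len(pool)} are free"
        )
    partner_order = [str(g) for g in rng.permutation(pool)]
    disease_edges: dict[Edge, float] = {}
    disease_partners: dict[str, list[str]] = {}
    pos = 0
    for g in disease_genes:
        partners = partner_order[pos : pos + cfg.disease_edges_per_gene]
        pos += cfg.disease_edges_per_gene
        disease_partners[g] = partners
        for p in partners:
            if cfg.direct_edge_strength:
                disease_edges[canonical_edge(g, p)] = cfg.direct_edge_strength

    shared_edges: dict[Edge, float] = {}
    attempts = 0
    while cfg.shared_edge_strength and len(shared_edges) < cfg.n_shared_edges \
            and attempts < 50 * cfg.n_shared_edges:
        attempts += 1
        a, b = rng.choice(pool, size=2, replace=False)
        e = canonical_edge(str(a), str(b))
        if e in disease_edges or e in shared_edges:
            continue
        shared_edges[e] = cfg.shared_edge_strength
    # cap per-gene shared degree at 1 so the near-singular disease hubs
    # stay jointly positive definite with the shared structure
    deg: dict[str, int] = {}
    capped = {}
    for e, s in sorted(shared_edges.items()):
        if deg.get(e[0], 0) < 1 and deg.get(e[1], 0) < 1:
            capped[e] = s
            deg[e[0]] = deg.get(e[0], 0) + 1
            deg[e[1]] = deg.get(e[1], 0) + 1
    shared_edges = capped

    normal_edges = {**chain_edges, **shared_edges}
    tumor_edges = {**normal_edges, **disease_edges}

    omega_t = _precision_matrix(cfg.n_genes, genes, tumor_edges)
    omega_n = _precision_matrix(cfg.n_genes, genes, normal_edges)

    # --- expression --------------------------------------------------------
    tumor_samples = [f"T{i:04d}" for i in range(1, cfg.n_tumor + 1)]
    normal_samples = [f"N{i:04d}" for i in range(1, cfg.n_normal + 1)]
    Zt = _sample_group(omega_t, cfg.n_tumor, rng)
    Zn = _sample_group(omega_n, cfg.n_normal, rng)
    # standardise by each group's theoretical per-gene SD so hub genes (whose
    # marginal latent variance is inflated by near-singular precision rows)
    # do not dominate the non-linear transform; correlations are unchanged
    Zt /= np.sqrt(np.diag(np.linalg.inv(omega_t)))[:, None]
    Zn /= np.sqrt(np.diag(np.linalg.inv(omega_n)))[:, None]
    gene_idx = {g: i for i, g in enumerate(genes)}
    if cfg.disease_expression_shift:
        for g in disease_genes:
            Zt[gene_idx[g]] += cfg.disease_expression_shift
    Z = np.hstack([Zt, Zn])
    if cfg.fpkm_transform:
        mu = rng.normal(1.0, 1.0, size=(cfg.n_genes, 1))  # per-gene log baseline
        values = np.exp(mu + cfg.fpkm_log_sd * Z)
    else:
        values = Z - Z.min() + 0.01
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=tumor_samples + normal_samples)
    )
    groups = SampleGroups(
        {**{s: "tumor" for s in tumor_samples}, **{s: "normal" for s in normal_samples}}
    )

    # --- methylation -------------------------------------------------------
    lo, hi = cfg.sites_per_gene
    site_rows = []
    site_gene: dict[str, str] = {}
    sites_of: dict[str, list[str]] = {}
    counter = 0
    for g in genes:
        k = int(rng.integers(lo, hi + 1))
        sites_of[g] = []
        for _ in range(k):
            counter += 1
            sid = f"cg{counter:07d}"
            sites_of[g].append(sid)
            site_gene[sid] = g

    # per-disease-gene tumor-only latent factor shared by the gene's and its
    # partners' sites; loading chosen so the squashed site-site correlation
    # lands near diff_meth_effect
    # aim the *latent* site-site correlation slightly above the target score:
    # the logistic squash and the finite-sample normal-group correlation both
    # eat into the realised |r_tumor - r_normal|
    lam = 1.0
    rho = min(0.95, cfg.diff_meth_effect + 0.1)
    resid_sd = float(np.sqrt(lam**2 * (1.0 - rho) / max(rho, 1e-6)))
    factor_t = {g: rng.standard_normal(cfg.n_tumor) for g in disease_genes}
    site_factor: dict[str, list[str]] = {}
    for g in disease_genes:
        for s in sites_of[g]:
            site_factor.setdefault(s, []).append(g)
        for p in disease_partners[g]:
            for s in sites_of[p]:
                site_factor.setdefault(s, []).append(g)

    n_all = cfg.n_tumor + cfg.n_normal
    all_samples = tumor_samples + normal_samples
    site_ids = sorted(site_gene)
    meth_vals = np.empty((len(site_ids), n_all))
    for i, sid in enumerate(site_ids):
        base = rng.normal(0.0, 0.3)  # per-site baseline methylation offset
        z = rng.standard_normal(n_all) * resid_sd
        factors = site_factor.get(sid, [])
        if factors:
            # load on the first owning factor only, to avoid dilution
            z[: cfg.n_tumor] += lam * factor_t[factors[0]]
            z[cfg.n_tumor :] += lam * rng.standard_normal(cfg.n_normal)
        else:
            z += lam * rng.standard_normal(n_all) * 0.5
        meth_vals[i] = _logistic(base + z)
    meth = MethylationMatrix(
        pd.DataFrame(meth_vals, index=site_ids, columns=all_samples),
        pd.Series({s: site_gene[s] for s in site_ids}, name="gene"),
    )

    differential_meth_edges = set(disease_edges)

    # --- mutations ---------------------------------------------------------
    records = []
    for g in genes:
        rate = cfg.disease_mutation_rate if g in disease_genes else cfg.background_mutation_rate
        hits = rng.random(cfg.n_tumor) < rate
        for s, hit in zip(tumor_samples, hits):
            if hit:
                records.append({"gene": g, "sample": s})
    mut = MutationTable(
        pd.DataFrame(records, columns=["gene", "sample"]), list(tumor_samples)
    )

    # --- PPI scaffold ------------------------------------------------------
    ppi = nx.Graph()
    structural = set(tumor_edges) | indirect_pairs
    for a, b in sorted(structural):
        ppi.add_edge(a, b, confidence=int(rng.integers(600, 1000)))
    target_edges = int(cfg.background_degree * cfg.n_genes / 2)
    attempts = 0
    while ppi.number_of_edges() < target_edges and attempts < 50 * target_edges:
        attempts += 1
        a, b = rng.choice(genes, size=2, replace=False)
        e = canonical_edge(str(a), str(b))
        if ppi.has_edge(*e):
            continue
        ppi.add_edge(*e, confidence=int(rng.integers(600, 1000)))

    truth = GroundTruth(
        disease_genes=set(disease_genes),
        direct_edges_tumor=set(tumor_edges),
        direct_edges_normal=set(normal_edges),
        indirect_pairs=indirect_pairs,
        differential_meth_edges=differential_meth_edges,
    )
    dataset = OmicsDataset(expr, groups, meth, mut, ppi)
    return dataset, truth


# ---------------------------------------------------------------------------
# writing a dataset in the readers' input dialects

def write_dataset(dataset: OmicsDataset, truth: GroundTruth, out_dir) -> dict[str, str]:
    """Write the four input files plus the ground-truth JSON; returns paths."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "methylation": out / "methylation.tsv",
        "methylation_annotation": out / "methylation_annotation.tsv",
        "mutations": out / "mutations.maf",
        "ppi": out / "ppi_links.txt",
        "ground_truth": out / "ground_truth.json",
    }
    dataset.expression.values.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    with open(paths["labels"], "w") as fh:
        for s in dataset.expression.samples:
            fh.write(f"{s}\t{dataset.groups.group(s)}\n")
    dataset.methylation.values.to_csv(paths["methylation"], sep="\t", float_format="%.6g")
    dataset.methylation.site_gene.to_csv(
        paths["methylation_annotation"], sep="\t", header=False
    )
    maf = dataset.mutations.records.rename(
        columns={"gene": "Hugo_Symbol", "sample": "Tumor_Sample_Barcode"}
    )
    maf.to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["ppi"], "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b in sorted(canonical_edge(x, y) for x, y in dataset.ppi.edges()):
            fh.write(f"{a} {b} {dataset.ppi[a][b]['confidence']}\n")
    paths["ground_truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# end-to-end recovery

#: degree thresholds matched to the synthetic network's planted hub degrees
SYNTHETIC_RANKING = RankingConfig(diff_pcorn_min_degree=6, diff_mn_min_degree=4, top_k=10)


def null_config(seed: int = 0) -> SyntheticConfig:
    """A no-signal configuration: no group-specific structure anywhere."""
    return SyntheticConfig(
        direct_edge_strength=0.0,
        disease_expression_shift=0.0,
        disease_mutation_rate=SyntheticConfig().background_mutation_rate,
        diff_meth_effect=0.0,
        seed=seed,
    )


@dataclass
class RecoveryReport:
    """Pipeline performance against the planted ground truth."""

    selected: list[str]
    disease_gene_recall: float
    disease_gene_precision: float
    indirect_removed_fraction: float
    direct_retained_fraction: float
    counts: dict[str, int] = field(default_factory=dict)


def recover(
    dataset: OmicsDataset,
    truth: GroundTruth,
    *,
    significance: SignificanceConfig | None = None,
    diff_cfg: DiffNetworkConfig | None = None,
    ranking: RankingConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> RecoveryReport:
    """Run the full pipeline on a generated dataset and score it."""
    from . import corrnet, diffnet, preprocess, ranking as rank_mod

    sig = significance or SignificanceConfig()
    rcfg = ranking or SYNTHETIC_RANKING
    expr = preprocess.filter_expressed_genes(dataset.expression, preprocess_cfg)
    meth = preprocess.filter_methylation_sites(dataset.methylation)
    background = preprocess.build_background_network(dataset.ppi, expr, preprocess_cfg)

    caches = {
        g: corrnet.PearsonCache(expr, dataset.groups, g) for g in ("tumor", "normal")
    }
    pccn = {
        g: corrnet.build_pccn(expr, background, dataset.groups, g, sig, cache=caches[g])
        for g in ("tumor", "normal")
    }
    pcorn = {
        g: corrnet.build_pcorn(pccn[g], expr, dataset.groups, g, sig, cache=caches[g])
        for g in ("tumor", "normal")
    }
    diff_pcorn = diffnet.diff_network(pcorn["tumor"], pcorn["normal"])
    diff_mn = diffnet.build_diff_mn(diff_pcorn, meth, dataset.groups, diff_cfg)
    ranked = rank_mod.select_disease_module(diff_pcorn, diff_mn, dataset.mutations, rcfg)

    selected = set(ranked.selected)
    recall = len(selected & truth.disease_genes) / max(len(truth.disease_genes), 1)
    precision = len(selected & truth.disease_genes) / max(len(selected), 1)

    removed, present = 0, 0
    retained, planted_in_pccn = 0, 0
    for group, direct in (
        ("tumor", truth.direct_edges_tumor),
        ("normal", truth.direct_edges_normal),
    ):
        for e in truth.indirect_pairs:
            if pccn[group].has_edge(*e):
                present += 1
                if not pcorn[group].has_edge(*e):
                    removed += 1
        for e in direct:
            if pccn[group].has_edge(*e):
                planted_in_pccn += 1
                if pcorn[group].has_edge(*e):
                    retained += 1

    return RecoveryReport(
        selected=ranked.selected,
        disease_gene_recall=recall,
        disease_gene_precision=precision,
        indirect_removed_fraction=removed / present if present else float("nan"),
        direct_retained_fraction=retained / planted_in_pccn if planted_in_pccn else float("nan"),
        counts={
            "background_edges": background.number_of_edges(),
            "pccn_tumor_edges": pccn["tumor"].number_of_edges(),
            "pccn_normal_edges": pccn["normal"].number_of_edges(),
            "pcorn_tumor_edges": pcorn["tumor"].number_of_edges(),
            "pcorn_normal_edges": pcorn["normal"].number_of_edges(),
            "diff_pcorn_edges": diff_pcorn.number_of_edges(),
            "diff_mn_edges": diff_mn.number_of_edges(),
            "overlap_genes": len(ranked.entries),
            "selected_genes": len(ranked.selected),
        },
    )
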