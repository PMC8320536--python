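"""End-to-end orchestration with per-stage file handoff.

Stages run in order -- preprocess, pccn, pcorn, diffnet, diffmn, rank,
validate -- each reading the previous stage's files from the output
directory and writing its own, so large runs are resumable and toy runs
inspectable.  A manifest JSON records every stage's counts and parameters;
re-running with the same inputs, config and seed reproduces it byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import networkx as nx

from . import corrnet, diffnet, io, preprocess, ranking, simulate, validation
from .config import PipelineConfig
from .datatypes import (
    DataError,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    OmicsDataset,
    SampleGroups,
)

log = logging.getLogger(__name__)

STAGES = ("preprocess", "pccn", "pcorn", "diffnet", "diffmn", "rank", "validate")


class MissingStageError(DataError):
    """A stage was invoked before its upstream stage produced its files."""


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"missing {path.name}; run the '{stage}' stage first"
        )
    return path


def _load_manifest(out: Path) -> dict:
    mpath = out / "manifest.json"
    return json.loads(mpath.read_text()) if mpath.exists() else {}


def _save_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _load_inputs(cfg: PipelineConfig) -> OmicsDataset:
    if cfg.expression_path is None:
        raise DataError("no expression_path configured; run 'simulate' or point to data")
    expr, groups = io.read_expression(
        cfg.expression_path, cfg.label_path, barcode_prefix_len=cfg.barcode_prefix_len
    )
    meth = io.read_methylation(
        cfg.methylation_path,
        cfg.methylation_annotation_path,
        barcode_prefix_len=cfg.barcode_prefix_len,
    )
    mut = io.read_mutations(cfg.mutation_path, barcode_prefix_len=cfg.barcode_prefix_len)
    ppi = io.read_ppi(cfg.ppi_path)
    return OmicsDataset(expr, groups, meth, mut, ppi)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    syn = cfg.synthetic
    syn.seed = cfg.seed if cfg.seed is not None else syn.seed
    dataset, truth = simulate.generate(syn)
    paths = simulate.write_dataset(dataset, truth, out / "inputs")
    cfg.expression_path = paths["expression"]
    cfg.label_path = paths["labels"]
    cfg.methylation_path = paths["methylation"]
    cfg.methylation_annotation_path = paths["methylation_annotation"]
    cfg.mutation_path = paths["mutations"]
    cfg.ppi_path = paths["ppi"]
    manifest = _load_manifest(out)
    manifest["simulate"] = {
        "n_genes": syn.n_genes,
        "n_tumor": syn.n_tumor,
        "n_normal": syn.n_normal,
        "n_disease_genes": syn.n_disease_genes,
        "seed": syn.seed,
        "paths": paths,
    }
    _save_manifest(out, manifest)
    return manifest["simulate"]


def stage_preprocess(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    dataset = _load_inputs(cfg)
    expr = preprocess.filter_expressed_genes(dataset.expression, cfg.preprocess)
    meth = preprocess.filter_methylation_sites(dataset.methylation)
    background = preprocess.build_background_network(dataset.ppi, expr, cfg.preprocess)
    expr.values.to_csv(out / "expression_filtered.tsv", sep="\t", float_format="%.8g")
    meth.values.to_csv(out / "methylation_filtered.tsv", sep="\t", float_format="%.8g")
    meth.site_gene.to_csv(out / "methylation_sites.tsv", sep="\t", header=False)
    with open(out / "labels.tsv", "w") as fh:
        for s in expr.samples:
            fh.write(f"{s}\t{dataset.groups.group(s)}\n")
    dataset.mutations.records.to_csv(out / "mutations_collapsed.tsv", sep="\t", index=False)
    (out / "mutation_samples.txt").write_text(
        "".join(f"{s}\n" for s in dataset.mutations.sample_universe)
    )
    io.write_network(background, out / "background.tsv")
    manifest = _load_manifest(out)
    manifest["preprocess"] = {
        "genes_kept": len(expr.genes),
        "sites_kept": len(meth.sites),
        "background_edges": background.number_of_edges(),
        "background_nodes": background.number_of_nodes(),
        "config": asdict(cfg.preprocess),
    }
    _save_manifest(out, manifest)
    return manifest["preprocess"]


def _load_stage_expr(out: Path) -> tuple[ExpressionMatrix, SampleGroups]:
    expr, groups = io.read_expression(
        _require(out / "expression_filtered.tsv", "preprocess"),
        _require(out / "labels.tsv", "preprocess"),
    )
    return expr, groups


def stage_pccn(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    expr, groups = _load_stage_expr(out)
    background = io.read_network(_require(out / "background.tsv", "preprocess"))
    manifest = _load_manifest(out)
    entry = {}
    for group in ("tumor", "normal"):
        net = corrnet.build_pccn(expr, background, groups, group, cfg.significance)
        io.write_network(net, out / f"pccn_{group}.tsv")
        entry[group] = {"edges": net.number_of_edges(), "nodes": net.number_of_nodes()}
    entry["config"] = asdict(cfg.significance)
    manifest["pccn"] = entry
    _save_manifest(out, manifest)
    return entry


def stage_pcorn(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    for group in ("tumor", "normal"):
        _require(out / f"pccn_{group}.tsv", "pccn")
    expr, groups = _load_stage_expr(out)
    manifest = _load_manifest(out)
    entry = {}
    for group in ("tumor", "normal"):
        pccn = io.read_network(_require(out / f"pccn_{group}.tsv", "pccn"))
        net = corrnet.build_pcorn(pccn, expr, groups, group, cfg.significance)
        io.write_network(net, out / f"pcorn_{group}.tsv")
        entry[group] = {"edges": net.number_of_edges(), "nodes": net.number_of_nodes()}
    manifest["pcorn"] = entry
    _save_manifest(out, manifest)
    return entry


def stage_diffnet(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    nets = {
        g: io.read_network(_require(out / f"pcorn_{g}.tsv", "pcorn"))
        for g in ("tumor", "normal")
    }
    diff = diffnet.diff_network(nets["tumor"], nets["normal"])
    io.write_network(diff, out / "diff_pcorn.tsv")
    manifest = _load_manifest(out)
    manifest["diffnet"] = {
        "edges": diff.number_of_edges(),
        "nodes": diff.number_of_nodes(),
        "tumor_only": sum(
            1 for _, _, d in diff.edges(data=True) if d["origin"] == "tumor_only"
        ),
    }
    _save_manifest(out, manifest)
    return manifest["diffnet"]


def stage_diffmn(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    diff = io.read_network(_require(out / "diff_pcorn.tsv", "diffnet"))
    meth_values = _require(out / "methylation_filtered.tsv", "preprocess")
    meth = io.read_methylation(meth_values, out / "methylation_sites.tsv")
    _, groups = _load_stage_expr(out)
    mn = diffnet.build_diff_mn(diff, meth, groups, cfg.diff_network)
    io.write_network(mn, out / "diff_mn.tsv")
    manifest = _load_manifest(out)
    manifest["diffmn"] = {
        "edges": mn.number_of_edges(),
        "nodes": mn.number_of_nodes(),
        "config": asdict(cfg.diff_network),
    }
    _save_manifest(out, manifest)
    return manifest["diffmn"]


def stage_rank(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    diff = io.read_network(_require(out / "diff_pcorn.tsv", "diffnet"))
    mn = io.read_network(_require(out / "diff_mn.tsv", "diffmn"))
    records = _require(out / "mutations_collapsed.tsv", "preprocess")
    import pandas as pd

    rec_df = pd.read_csv(records, sep="\t")
    if rec_df.empty:
        rec_df = pd.DataFrame(columns=["gene", "sample"])
    universe = [
        s for s in (out / "mutation_samples.txt").read_text().splitlines() if s
    ]
    mut = MutationTable(rec_df.astype(str) if not rec_df.empty else rec_df, universe)
    result = ranking.select_disease_module(diff, mn, mut, cfg.ranking)
    result.entries.to_csv(out / "ranked_candidates.tsv", sep="\t", index=False)
    io.write_gene_list(result.selected, out / "selected_genes.txt")
    manifest = _load_manifest(out)
    manifest["rank"] = {
        "candidate_set1": int(
            len(ranking.degree_filter(diff, cfg.ranking.diff_pcorn_min_degree))
        ),
        "candidate_set2": int(
            len(ranking.degree_filter(mn, cfg.ranking.diff_mn_min_degree))
        ),
        "overlap": int(len(result.entries)),
        "selected": result.selected,
        "config": asdict(cfg.ranking),
    }
    _save_manifest(out, manifest)
    return manifest["rank"]


def stage_validate(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    expr, groups = _load_stage_expr(out)
    selected = io.read_gene_list(_require(out / "selected_genes.txt", "rank"))
    report: dict = {}
    if selected:
        cls = validation.classify_cv(expr, selected, groups, seed=cfg.seed)
        clu = validation.cluster_samples(expr, selected, groups)
        report["auc"] = cls.auc
        report["fold_count"] = cls.fold_count
        report["roc_points"] = cls.roc_points
        report["normal_cluster_recall"] = clu.normal_cluster_recall
        tests = validation.per_gene_differential_test(expr, selected, groups)
        tests.to_csv(out / "per_gene_tests.tsv", sep="\t", index=False)
    universe = set(expr.genes)
    report["enrichment"] = {}
    for name, path in (cfg.reference_gene_lists or {}).items():
        ref = io.read_gene_list(path)
        res = validation.enrichment_test(selected, ref, universe)
        report["enrichment"][name] = asdict(res)
    (out / "validation.json").write_text(json.dumps(report, indent=1))
    manifest = _load_manifest(out)
    manifest["validate"] = {k: v for k, v in report.items() if k != "roc_points"}
    _save_manifest(out, manifest)
    return manifest["validate"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "pccn": stage_pccn,
    "pcorn": stage_pcorn,
    "diffnet": stage_diffnet,
    "diffmn": stage_diffmn,
    "rank": stage_rank,
    "validate": stage_validate,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    if name not in _STAGE_FUNCS:
        raise DataError(f"unknown stage {name!r}; choose from {sorted(_STAGE_FUNCS)}")
    return _STAGE_FUNCS[name](cfg)


def run_pipeline(cfg: PipelineConfig, *, simulate_inputs: bool = False) -> dict:
    """Run every stage in order; returns the manifest."""
    out = _out(cfg)
    if simulate_inputs:
        stage_simulate(cfg)
    for name in STAGES:
        log.info("=== stage %s ===", name)
        try:
            run_stage(name, cfg)
        except DataError:
            manifest = _load_manifest(out)
            manifest["failed_stage"] = name
            _save_manifest(out, manifest)
            raise
    return _load_manifest(out)
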