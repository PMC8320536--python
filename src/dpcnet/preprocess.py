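"""Filtering rules that turn raw inputs into analysis-ready matrices.

Three rules: keep genes expressed in strictly more than half of all samples;
keep CpG sites that map to exactly one gene and have no missing Beta values;
keep PPI edges with confidence strictly above 500 whose endpoints are both
expressed genes.  All counts are logged.
"""

from __future__ import annotations

import logging

import networkx as nx

from .config import PreprocessConfig
from .datatypes import DataError, ExpressionMatrix, MethylationMatrix

log = logging.getLogger(__name__)


def filter_expressed_genes(
    expr: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Keep genes expressed (value > presence threshold) in strictly more
    than ``min_expressed_fraction`` of the pooled samples."""
    cfg = cfg or PreprocessConfig()
    if expr.values.empty:
        raise DataError("empty expression matrix")
    n = len(expr.samples)
    frac = (expr.values > cfg.expression_presence_threshold).sum(axis=1) / n
    kept = expr.values.loc[frac > cfg.min_expressed_fraction]
    log.info("expression filter: kept %d / %d genes", len(kept), len(expr.genes))
    if kept.empty:
        raise DataError(
            "no gene passed the expression filter; lower min_expressed_fraction "
            "or expression_presence_threshold"
        )
    return ExpressionMatrix(kept)


def filter_methylation_sites(meth: MethylationMatrix) -> MethylationMatrix:
    """Keep sites annotated to exactly one gene and with no missing Betas."""
    single_gene = ~meth.site_gene.str.contains(";") & (meth.site_gene.str.len() > 0)
    single_gene = single_gene.reindex(meth.values.index, fill_value=False)
    complete = ~meth.values.isna().any(axis=1)
    keep = meth.values.index[single_gene.to_numpy() & complete.to_numpy()]
    log.info("methylation filter: kept %d / %d sites", len(keep), len(meth.sites))
    return MethylationMatrix(meth.values.loc[keep], meth.site_gene.loc[keep])


def build_background_network(
    ppi: nx.Graph, expr: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> nx.Graph:
    """Confidence- and expression-restricted PPI: the background network.

    Edges need confidence strictly greater than ``ppi_min_confidence`` and
    both endpoints among the (already filtered) expressed genes; isolated
    nodes are removed.
    """
    cfg = cfg or PreprocessConfig()
    genes = set(expr.genes)
    net = nx.Graph()
    for a, b, d in ppi.edges(data=True):
        if d.get("confidence", 0) > cfg.ppi_min_confidence and a in genes and b in genes:
            net.add_edge(a, b, confidence=d["confidence"])
    log.info(
        "background network: %d / %d edges kept, %d nodes",
        net.number_of_edges(), ppi.number_of_edges(), net.number_of_nodes(),
    )
    if net.number_of_edges() == 0:
        raise DataError(
            "background network is empty; check ppi_min_confidence and that "
            "PPI identifiers match expression gene symbols"
        )
    return net
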