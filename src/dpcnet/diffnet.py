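"""Differential networks.

*Diff-PCORN* is the symmetric difference of the tumor and normal
partial-correlation networks: edges present in exactly one group, tagged
``tumor_only`` / ``normal_only``.  These rewired dependencies are the
method's candidate disease signal.

*Diff-MN* re-scores every Diff-PCORN edge in methylation space: for each
cross-gene pair of CpG sites (one site per gene side) the Pearson
correlation of Beta values is computed within tumor and within normal
samples, and the edge score is the maximum |r_tumor - r_normal| over site
pairs.  Edges scoring strictly above the threshold (default 0.7) form
Diff-MN.  Edges whose genes lack methylation coverage are skipped, not
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .config import DiffNetworkConfig
from .datatypes import (
    DataError,
    MethylationMatrix,
    SampleGroups,
    canonical_edge,
    sorted_edges,
)

log = logging.getLogger(__name__)

_EPS = 1e-12


def diff_network(net_tumor: nx.Graph, net_normal: nx.Graph) -> nx.Graph:
    """Symmetric difference of the two networks with origin tags."""
    out = nx.Graph()
    tumor_edges = {canonical_edge(a, b) for a, b in net_tumor.edges()}
    normal_edges = {canonical_edge(a, b) for a, b in net_normal.edges()}
    for a, b in sorted(tumor_edges - normal_edges):
        out.add_edge(a, b, origin="tumor_only")
    for a, b in sorted(normal_edges - tumor_edges):
        out.add_edge(a, b, origin="normal_only")
    n_common = len(tumor_edges & normal_edges)
    log.info("Diff network: %d edges (%d tumor-only), %d common edges removed",
             out.number_of_edges(),
             sum(1 for _, _, d in out.edges(data=True) if d["origin"] == "tumor_only"),
             n_common)
    return out


@dataclass
class DiffMethEdge:
    """Differential co-methylation evidence for one gene pair."""

    pair: tuple[str, str]
    score: float
    best_site_pair: tuple[str, str]
    n_site_pairs: int


def _group_corr(values: np.ndarray) -> float:
    """Pearson r of two site rows; constant rows give r = 0 (flagged once)."""
    x, y = values
    if x.std() < _EPS or y.std() < _EPS:
        return 0.0
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def edge_methylation_score(
    pair: tuple[str, str],
    meth: MethylationMatrix,
    groups: SampleGroups,
) -> DiffMethEdge:
    """Max |r_tumor - r_normal| over all cross-gene CpG site pairs.

    Symmetric in gene order and invariant to site enumeration order (ties on
    the max broken by sorted site-pair identity).
    """
    a, b = canonical_edge(*pair)
    sites_a = sorted(meth.sites_for_gene(a))
    sites_b = sorted(meth.sites_for_gene(b))
    if not sites_a or not sites_b:
        raise DataError(f"gene without methylation sites on edge {(a, b)}")
    tumor = [s for s in meth.samples if groups.group(s) == "tumor"]
    normal = [s for s in meth.samples if groups.group(s) == "normal"]
    if len(tumor) < 3 or len(normal) < 3:
        raise DataError("each group needs at least 3 methylation samples")
    vt = meth.values[tumor]
    vn = meth.values[normal]
    best: tuple[float, tuple[str, str]] | None = None
    for sa in sites_a:
        for sb in sites_b:
            rt = _group_corr(np.vstack([vt.loc[sa], vt.loc[sb]]))
            rn = _group_corr(np.vstack([vn.loc[sa], vn.loc[sb]]))
            d = abs(rt - rn)
            if best is None or d > best[0] + _EPS:
                best = (d, (sa, sb))
    assert best is not None
    return DiffMethEdge((a, b), best[0], best[1], len(sites_a) * len(sites_b))


def build_diff_mn(
    diff_pcorn: nx.Graph,
    meth: MethylationMatrix,
    groups: SampleGroups,
    cfg: DiffNetworkConfig | None = None,
) -> nx.Graph:
    """Diff-PCORN edges whose differential methylation score exceeds the
    threshold (strict >); uncovered edges are skipped and counted."""
    cfg = cfg or DiffNetworkConfig()
    covered_genes = set(meth.site_gene.unique())
    out = nx.Graph()
    skipped = 0
    scored = 0
    for a, b in sorted_edges(diff_pcorn):
        if a not in covered_genes or b not in covered_genes:
            skipped += 1
            continue
        rec = edge_methylation_score((a, b), meth, groups)
        scored += 1
        if rec.score > cfg.meth_score_threshold:
            out.add_edge(
                a, b,
                score=float(rec.score),
                site_a=rec.best_site_pair[0],
                site_b=rec.best_site_pair[1],
                n_site_pairs=int(rec.n_site_pairs),
            )
    log.info("Diff-MN: %d / %d scoreable edges kept (> %g); %d edges without coverage",
             out.number_of_edges(), scored, cfg.meth_score_threshold, skipped)
    return out
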