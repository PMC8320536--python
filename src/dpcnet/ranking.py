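"""Candidate selection and mutation-frequency ranking.

Three steps: hub genes of Diff-PCORN (degree strictly > 30), hub genes of
Diff-MN (degree strictly > 15), their overlap; the overlap is ordered by
descending somatic variation frequency (fraction of variant-called samples
in which the gene carries at least one mutation), ties broken by descending
Diff-PCORN degree, residual ties lexicographically.  The first ``top_k``
genes are the disease module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .config import RankingConfig
from .datatypes import DataError, MutationTable

log = logging.getLogger(__name__)


def degree_filter(net: nx.Graph, min_degree: int) -> set[str]:
    """Genes with degree strictly greater than ``min_degree``."""
    return {g for g, d in net.degree() if d > min_degree}


def variation_frequency(mut: MutationTable) -> dict[str, float]:
    """Per-gene fraction of universe samples carrying >= 1 mutation."""
    n = len(mut.sample_universe)
    if n == 0:
        raise DataError("mutation table has an empty sample universe")
    counts = mut.records.groupby("gene")["sample"].nunique()
    return {g: c / n for g, c in counts.items()}


@dataclass
class RankedCandidates:
    """Ordered overlap genes with the evidence that produced the ordering."""

    entries: pd.DataFrame  # rank, gene, variation_frequency, degrees, selected
    selected: list[str]


def rank_candidates(
    set1: set[str],
    set2: set[str],
    freq: dict[str, float],
    diff_pcorn: nx.Graph,
    diff_mn: nx.Graph,
    cfg: RankingConfig | None = None,
) -> RankedCandidates:
    """Order the overlap of the two candidate sets and pick the top genes."""
    cfg = cfg or RankingConfig()
    overlap = sorted(set1 & set2)
    if not overlap:
        log.warning("candidate overlap is empty")
        cols = ["rank", "gene", "variation_frequency",
                "diff_pcorn_degree", "diff_mn_degree", "selected"]
        return RankedCandidates(pd.DataFrame(columns=cols), [])
    rows = [
        {
            "gene": g,
            "variation_frequency": float(freq.get(g, 0.0)),
            "diff_pcorn_degree": int(diff_pcorn.degree(g)) if g in diff_pcorn else 0,
            "diff_mn_degree": int(diff_mn.degree(g)) if g in diff_mn else 0,
        }
        for g in overlap
    ]
    df = pd.DataFrame(rows).sort_values(
        ["variation_frequency", "diff_pcorn_degree", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", df.index + 1)
    df["selected"] = df["rank"] <= cfg.top_k
    selected = df.loc[df["selected"], "gene"].tolist()
    log.info("ranking: %d overlap genes, %d selected", len(df), len(selected))
    return RankedCandidates(df, selected)


def select_disease_module(
    diff_pcorn: nx.Graph,
    diff_mn: nx.Graph,
    mutations: MutationTable,
    cfg: RankingConfig | None = None,
) -> RankedCandidates:
    """The full three-step selection from the two networks and the variants."""
    cfg = cfg or RankingConfig()
    set1 = degree_filter(diff_pcorn, cfg.diff_pcorn_min_degree)
    set2 = degree_filter(diff_mn, cfg.diff_mn_min_degree)
    log.info("candidate sets: %d (Diff-PCORN > %d), %d (Diff-MN > %d)",
             len(set1), cfg.diff_pcorn_min_degree, len(set2), cfg.diff_mn_min_degree)
    freq = variation_frequency(mutations)
    return rank_candidates(set1, set2, freq, diff_pcorn, diff_mn, cfg)
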