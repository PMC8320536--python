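"""Readers and writers for the four input tables and for network edge lists.

Input dialects
--------------
* expression / methylation: tab-separated matrix, first column the gene
  symbol / CpG-site id, header row the sample ids;
* sample labels: two-column TSV ``sample<TAB>group`` (tumor/normal);
* PPI: whitespace-separated STRING protein-links dialect with header
  ``protein1 protein2 combined_score`` (scores are integers 1-999);
* mutations: MAF-like TSV with configurable gene / sample-barcode columns
  (defaults ``Hugo_Symbol`` / ``Tumor_Sample_Barcode``).

All network edge lists are written sorted on the canonical (lexicographic)
gene pair so outputs are byte-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    DataError,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    SampleGroups,
    canonical_edge,
    sorted_edges,
)

log = logging.getLogger(__name__)


def _truncate(sample: str, prefix_len: int | None) -> str:
    return sample if prefix_len is None else sample[:prefix_len]


def read_expression(
    path: str | Path,
    label_path: str | Path,
    *,
    barcode_prefix_len: int | None = None,
) -> tuple[ExpressionMatrix, SampleGroups]:
    """Read an FPKM-like matrix plus its tumor/normal sample labeling.

    Duplicate gene symbols keep the row with the highest mean (a warning is
    logged). ``barcode_prefix_len`` optionally truncates sample ids so that
    barcodes from different assays can be matched on a common prefix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [_truncate(str(c), barcode_prefix_len) for c in df.columns]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise DataError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
    df = df.astype(float)
    if df.isna().to_numpy().any():
        i, j = [x[0] for x in df.isna().to_numpy().nonzero()]
        raise DataError(
            f"missing expression value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )

    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        log.warning("expression matrix: %d duplicated gene row(s); keeping highest-mean row", n_dup)
        df = (
            df.assign(_mean=df.mean(axis=1))
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        df = df.sort_index()

    labels_df = pd.read_csv(label_path, sep="\t", header=None, names=["sample", "group"])
    labels = {
        _truncate(str(r.sample), barcode_prefix_len): str(r.group)
        for r in labels_df.itertuples()
    }
    unknown = [s for s in labels if s not in set(df.columns)]
    if unknown:
        raise DataError(f"label file names unknown sample(s): {unknown[:5]}")
    groups = SampleGroups(labels)
    groups.require_covers(df.columns)
    return ExpressionMatrix(df), groups


def read_ppi(
    path: str | Path,
    *,
    id_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a STRING-style weighted edge list into an undirected graph.

    Reciprocal duplicate rows collapse keeping the maximum score; self-loops
    are dropped. With ``id_map``, endpoints are translated to gene symbols
    and edges with an unmappable endpoint are dropped (count logged).
    """
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    need = {"protein1", "protein2", "combined_score"}
    if not need <= set(df.columns):
        raise DataError(f"PPI file needs columns {sorted(need)}; found {list(df.columns)}")
    scores = df["combined_score"].to_numpy()
    if ((scores < 1) | (scores > 999)).any():
        bad = scores[(scores < 1) | (scores > 999)][0]
        raise DataError(f"combined_score {bad} outside [1, 999]")

    net = nx.Graph()
    dropped_unmappable = 0
    dropped_self = 0
    for a, b, s in zip(df["protein1"], df["protein2"], df["combined_score"]):
        a, b = str(a), str(b)
        if id_map is not None:
            if a not in id_map or b not in id_map:
                dropped_unmappable += 1
                continue
            a, b = id_map[a], id_map[b]
        if a == b:
            dropped_self += 1
            continue
        u, v = canonical_edge(a, b)
        s = int(s)
        if net.has_edge(u, v):
            net[u][v]["confidence"] = max(net[u][v]["confidence"], s)
        else:
            net.add_edge(u, v, confidence=s)
    if dropped_unmappable:
        log.warning("PPI: dropped %d edge(s) with unmappable endpoints", dropped_unmappable)
    if dropped_self:
        log.info("PPI: dropped %d self-loop(s)", dropped_self)
    return net


def read_methylation(
    path: str | Path,
    annotation_path: str | Path,
    *,
    barcode_prefix_len: int | None = None,
) -> MethylationMatrix:
    """Read a raw Beta-value matrix and its site->gene annotation.

    Annotation strings (possibly ``GENE1;GENE2``) are preserved verbatim;
    multi-gene and missing-value filtering happens in preprocessing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [_truncate(str(c), barcode_prefix_len) for c in df.columns]
    df = df.apply(pd.to_numeric, errors="coerce")
    ann = pd.read_csv(annotation_path, sep="\t", header=None, names=["site", "gene"])
    site_gene = pd.Series(
        ann["gene"].astype(str).to_numpy(), index=ann["site"].astype(str), name="gene"
    )
    return MethylationMatrix(df, site_gene)


def read_mutations(
    path: str | Path,
    *,
    gene_column: str = "Hugo_Symbol",
    sample_column: str = "Tumor_Sample_Barcode",
    barcode_prefix_len: int | None = None,
) -> MutationTable:
    """Read a MAF-like variant table and collapse to (gene, sample) records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in (gene_column, sample_column):
        if col not in df.columns:
            raise DataError(f"mutation file is missing required column {col!r}")
    if df.empty:
        empty = pd.DataFrame(columns=["gene", "sample"])
        return MutationTable(empty, [])
    records = (
        pd.DataFrame(
            {
                "gene": df[gene_column].astype(str),
                "sample": [
                    _truncate(str(s), barcode_prefix_len) for s in df[sample_column]
                ],
            }
        )
        .drop_duplicates()
        .sort_values(["gene", "sample"])
        .reset_index(drop=True)
    )
    universe = sorted(records["sample"].unique())
    return MutationTable(records, universe)


# ---------------------------------------------------------------------------
# network edge-list round trip

_EDGE_KEY_TYPES = {
    "confidence": int,
    "r": float,
    "p": float,
    "p_adj": float,
    "r_partial": float,
    "t": float,
    "order": int,
    "k_selected": str,
    "origin": str,
    "score": float,
    "site_a": str,
    "site_b": str,
    "n_site_pairs": int,
}


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write an edge list as TSV: gene_a, gene_b, then any edge attributes."""
    attr_keys = sorted({k for _, _, d in net.edges(data=True) for k in d})
    rows = []
    for a, b in sorted_edges(net):
        d = net[a][b]
        rows.append([a, b] + [d.get(k, "") for k in attr_keys])
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b"] + attr_keys)
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> nx.Graph:
    """Read an edge list written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    net = nx.Graph()
    attr_keys = [c for c in df.columns if c not in ("gene_a", "gene_b")]
    for row in df.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        attrs = {}
        for k in attr_keys:
            raw = getattr(row, k)
            if raw == "":
                continue
            conv = _EDGE_KEY_TYPES.get(k, str)
            attrs[k] = conv(float(raw)) if conv is int else conv(raw)
        net.add_edge(a, b, **attrs)
    return net


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
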