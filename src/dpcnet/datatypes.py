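"""Core in-memory containers shared by every pipeline stage.

All matrices are pandas DataFrames (features in rows, samples in columns);
gene networks are undirected :class:`networkx.Graph` objects over gene
symbols, with per-edge attributes (``confidence``, ``r``, ``p``, ``p_adj``,
``origin`` ...) attached by the stage that created the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
GROUPS = (TUMOR, NORMAL)


class DataError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass(frozen=True)
class SampleGroups:
    """Tumor/normal labeling of samples.

    ``labels`` maps sample id -> ``"tumor"`` or ``"normal"``.
    """

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.labels.items() if g not in GROUPS}
        if bad:
            raise DataError(f"unknown group labels: {bad}")

    def group(self, sample: str) -> str:
        return self.labels[sample]

    def samples(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise DataError(f"unknown group {group!r}; expected one of {GROUPS}")
        return [s for s, g in self.labels.items() if g == group]

    def require_covers(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise DataError(
                f"{len(missing)} sample(s) have no group label, e.g. {missing[:5]}"
            )

    def require_both_groups(self, samples: Iterable[str]) -> None:
        samples = list(samples)
        self.require_covers(samples)
        present = {self.labels[s] for s in samples}
        if set(GROUPS) - present:
            raise DataError(
                f"both tumor and normal samples are required; found only {sorted(present)}"
            )


@dataclass
class ExpressionMatrix:
    """Gene expression on an FPKM-like non-negative scale (genes x samples)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate gene symbols: {list(dup)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise DataError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples])


@dataclass
class MethylationMatrix:
    """CpG-site Beta values in [0, 1] (sites x samples) plus a site->gene map.

    ``site_gene`` holds the raw annotation string per site (possibly
    semicolon-separated multi-gene); preprocessing resolves it to a single
    gene per retained site.
    """

    values: pd.DataFrame
    site_gene: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate CpG site ids")
        arr = self.values.to_numpy(dtype=float)
        bad = ((arr < 0) | (arr > 1)) & ~pd.isna(arr)
        if bad.any():
            i, j = [x[0] for x in bad.nonzero()]
            raise DataError(
                f"Beta value out of [0,1] at site {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        missing = [s for s in self.values.index if s not in self.site_gene.index]
        if missing:
            raise DataError(f"sites without gene annotation: {missing[:5]}")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sites_for_gene(self, gene: str) -> list[str]:
        hits = self.site_gene[self.site_gene == gene]
        return [s for s in hits.index if s in self.values.index]


@dataclass
class MutationTable:
    """Collapsed somatic-variant table: one record per mutated (gene, sample)."""

    records: pd.DataFrame  # columns: gene, sample; unique pairs
    sample_universe: list[str]

    def __post_init__(self) -> None:
        need = {"gene", "sample"}
        if not need <= set(self.records.columns):
            raise DataError(f"mutation records need columns {sorted(need)}")
        universe = set(self.sample_universe)
        extra = set(self.records["sample"]) - universe
        if extra:
            raise DataError(
                f"records reference samples outside the universe: {sorted(extra)[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())


@dataclass
class OmicsDataset:
    """The four aligned inputs a full pipeline run consumes."""

    expression: ExpressionMatrix
    groups: SampleGroups
    methylation: MethylationMatrix
    mutations: MutationTable
    ppi: nx.Graph = field(default_factory=nx.Graph)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Lexicographically sorted gene pair; the canonical undirected edge key."""
    return (a, b) if a <= b else (b, a)


def sorted_edges(net: nx.Graph) -> list[tuple[str, str]]:
    return sorted(canonical_edge(a, b) for a, b in net.edges())
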