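"""Per-group correlation networks.

Two stages per sample group:

1. **PCCN** — for every background-PPI edge, the Pearson correlation of the
   two genes' expression over that group's samples; p-values from the
   Student-t transform ``t = r sqrt(n-2) / sqrt(1-r^2)``; Benjamini–Hochberg
   adjustment over all background edges jointly; keep adjusted p < 0.01.

2. **PCORN** — for every PCCN edge (i, j), the first-order partial
   correlation

       r_ij(k) = (r_ij - r_ik r_jk) / sqrt((1 - r_ik^2)(1 - r_jk^2))

   conditioning on single genes k.  The candidate set for k is the PCCN
   common neighborhood of i and j (the only genes the network itself offers
   as an explanation for the edge); the candidate minimising |r_ij(k)| is
   tested, so an edge survives only if no single neighbor explains it away.
   The test statistic is ``t = r sqrt(N - q - 2) / sqrt(1 - r^2)`` with
   ``q = 1`` (or 0 when the edge has no common neighbor, in which case the
   zero-order correlation is tested); Bonferroni adjustment over all PCCN
   edges jointly; keep adjusted p < 0.05.

An exhaustive mode (k ranges over every other gene in the matrix) is
available via ``SignificanceConfig.exhaustive_conditioning``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .config import SignificanceConfig
from .datatypes import DataError, ExpressionMatrix, SampleGroups, canonical_edge

log = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# elementary statistics

def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided Student-t p-value.

    A constant vector leaves r undefined; the pair is treated as
    non-significant (r = 0, p = 1) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise DataError("pearson_r_p needs two equal-length vectors with n >= 3")
    sx, sy = x.std(), y.std()
    if sx < _EPS or sy < _EPS:
        log.warning("constant vector in correlation; treating edge as non-significant")
        return 0.0, 1.0
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0 - _EPS:
        r = math.copysign(1.0, r)
    return r, _r_to_p(r, n, q=0)


def _r_to_p(r: float, n: int, q: int) -> float:
    """Two-sided p for a (partial) correlation via the Student-t transform."""
    df = n - q - 2
    if abs(r) >= 1.0 - _EPS:
        return 0.0
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def partial_t_statistic(r_partial: float, n_samples: int, order: int) -> tuple[float, float]:
    """t statistic and two-sided p for a partial correlation of given order."""
    df = n_samples - order - 2
    if df <= 0:
        raise DataError(f"need n_samples > order + 2; got n={n_samples}, q={order}")
    if abs(r_partial) > 1 + 1e-9:
        raise DataError("|r_partial| must be <= 1")
    r = float(np.clip(r_partial, -1.0, 1.0))
    if abs(r) >= 1.0 - _EPS:
        return math.inf if r > 0 else -math.inf, 0.0
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def first_order_partial(r_ij: float, r_ik: float, r_jk: float) -> float:
    """First-order partial correlation of (i, j) given k, clamped to [-1, 1].

    Raises when a conditioning correlation is degenerate (|r| = 1).
    """
    if abs(r_ik) >= 1.0 - _EPS or abs(r_jk) >= 1.0 - _EPS:
        raise DataError("degenerate conditioning: |r_ik| or |r_jk| is 1")
    denom = math.sqrt((1.0 - r_ik * r_ik) * (1.0 - r_jk * r_jk))
    return float(np.clip((r_ij - r_ik * r_jk) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# multiple-testing adjustments

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    _check_probs(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    _check_probs(p)
    return np.minimum(p * p.size, 1.0)


def _check_probs(p: np.ndarray) -> None:
    if p.size and ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# group-wise correlation cache

class PearsonCache:
    """Pairwise Pearson correlations for one group's samples, on demand.

    Rows are standardised once; any r(a, b) is then a dot product.  Constant
    genes are flagged: correlations involving them are reported as r = 0.
    """

    def __init__(self, expr: ExpressionMatrix, groups: SampleGroups, group: str):
        samples = [s for s in expr.samples if groups.group(s) == group]
        if len(samples) < 3:
            raise DataError(
                f"group {group!r} has {len(samples)} sample(s); at least 3 required"
            )
        self.n = len(samples)
        self.group = group
        X = expr.values[samples].to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        self.constant = (sd < _EPS).ravel()
        sd[sd < _EPS] = 1.0
        self._Z = (X - mu) / sd
        self._index = {g: i for i, g in enumerate(expr.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def r(self, a: str, b: str) -> float:
        ia, ib = self._index[a], self._index[b]
        if self.constant[ia] or self.constant[ib]:
            return 0.0
        v = float(self._Z[ia] @ self._Z[ib]) / self.n
        return float(np.clip(v, -1.0, 1.0))

    def r_many(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        ia = np.fromiter((self._index[a] for a, _ in pairs), dtype=int, count=len(pairs))
        ib = np.fromiter((self._index[b] for _, b in pairs), dtype=int, count=len(pairs))
        vals = np.einsum("ij,ij->i", self._Z[ia], self._Z[ib]) / self.n
        vals = np.clip(vals, -1.0, 1.0)
        vals[self.constant[ia] | self.constant[ib]] = 0.0
        return vals


# ---------------------------------------------------------------------------
# network builders

def build_pccn(
    expr: ExpressionMatrix,
    background: nx.Graph,
    groups: SampleGroups,
    group: str,
    cfg: SignificanceConfig | None = None,
    *,
    cache: PearsonCache | None = None,
) -> nx.Graph:
    """Pearson correlation network for one group over the background edges."""
    cfg = cfg or SignificanceConfig()
    cache = cache or PearsonCache(expr, groups, group)
    pairs = [canonical_edge(a, b) for a, b in background.edges()]
    pairs.sort()
    net = nx.Graph()
    if not pairs:
        return net
    missing = [p for p in pairs if p[0] not in cache or p[1] not in cache]
    if missing:
        raise DataError(
            f"background edge endpoints missing from expression matrix, e.g. {missing[0]}"
        )
    r = cache.r_many(pairs)
    const_edge = np.array(
        [cache.constant[cache._index[a]] or cache.constant[cache._index[b]] for a, b in pairs]
    )
    if const_edge.any():
        log.warning("PCCN(%s): %d edge(s) with a constant gene treated as null",
                    group, int(const_edge.sum()))
    p = np.array([_r_to_p(ri, cache.n, q=0) for ri in r])
    p[const_edge] = 1.0
    p_adj = bh_adjust(p)
    for (a, b), ri, pi, qi in zip(pairs, r, p, p_adj):
        if qi < cfg.pearson_alpha:
            net.add_edge(a, b, r=float(ri), p=float(pi), p_adj=float(qi))
    log.info("PCCN(%s): %d / %d edges significant (BH < %g)",
             group, net.number_of_edges(), len(pairs), cfg.pearson_alpha)
    return net


@dataclass
class PartialEdgeResult:
    """Surviving partial-correlation evidence for one tested edge."""

    pair: tuple[str, str]
    r_partial: float
    k_selected: str | None
    t: float
    p: float
    n_samples: int
    order: int
    p_adj: float = math.nan


def edge_partial_test(
    pair: tuple[str, str],
    pccn: nx.Graph,
    cache: PearsonCache,
    *,
    exhaustive: bool = False,
    all_genes: list[str] | None = None,
) -> PartialEdgeResult:
    """Most-conservative first-order partial-correlation test for one edge.

    Candidates k are the PCCN common neighbors of the endpoints (or every
    other gene in exhaustive mode); the k minimising |r_ij(k)| is tested
    (ties broken lexicographically).  With no candidate the zero-order
    correlation is tested (q = 0).
    """
    a, b = canonical_edge(*pair)
    if not pccn.has_edge(a, b):
        raise DataError(f"{(a, b)} is not a PCCN edge")
    if exhaustive:
        pool = all_genes if all_genes is not None else list(pccn.nodes)
        candidates = sorted(k for k in pool if k not in (a, b))
    else:
        candidates = sorted(set(pccn[a]) & set(pccn[b]) - {a, b})
    r_ij = cache.r(a, b)
    best_k, best_r = None, None
    for k in candidates:
        r_ik, r_jk = cache.r(a, k), cache.r(b, k)
        try:
            r_p = first_order_partial(r_ij, r_ik, r_jk)
        except DataError:
            continue  # degenerate conditioning: skip this k
        if best_r is None or abs(r_p) < abs(best_r):
            best_k, best_r = k, r_p
    if best_k is None:
        if candidates:
            log.warning("edge %s: all conditioning candidates degenerate; order-0 fallback", (a, b))
        t, p = partial_t_statistic(r_ij, cache.n, 0)
        return PartialEdgeResult((a, b), r_ij, None, t, p, cache.n, 0)
    t, p = partial_t_statistic(best_r, cache.n, 1)
    return PartialEdgeResult((a, b), best_r, best_k, t, p, cache.n, 1)


def build_pcorn(
    pccn: nx.Graph,
    expr: ExpressionMatrix,
    groups: SampleGroups,
    group: str,
    cfg: SignificanceConfig | None = None,
    *,
    cache: PearsonCache | None = None,
) -> nx.Graph:
    """Partial-correlation network: PCCN edges surviving the Bonferroni test."""
    cfg = cfg or SignificanceConfig()
    cache = cache or PearsonCache(expr, groups, group)
    pairs = sorted(canonical_edge(a, b) for a, b in pccn.edges())
    results = [
        edge_partial_test(pair, pccn, cache,
                          exhaustive=cfg.exhaustive_conditioning,
                          all_genes=expr.genes if cfg.exhaustive_conditioning else None)
        for pair in pairs
    ]
    p_adj = bonferroni_adjust([res.p for res in results])
    net = nx.Graph()
    for res, q in zip(results, p_adj):
        res.p_adj = float(q)
        if q < cfg.partial_alpha:
            a, b = res.pair
            net.add_edge(
                a, b,
                r=float(cache.r(a, b)),
                r_partial=float(res.r_partial),
                k_selected="" if res.k_selected is None else res.k_selected,
                t=float(res.t),
                p=float(res.p),
                p_adj=float(q),
                order=int(res.order),
            )
    log.info("PCORN(%s): %d / %d edges retained (Bonferroni < %g)",
             group, net.number_of_edges(), len(pairs), cfg.partial_alpha)
    return net
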