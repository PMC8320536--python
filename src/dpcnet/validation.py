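"""Verification statistics for an identified disease module.

* hypergeometric enrichment of the module in a reference cancer-gene list
  (upper tail, computed as 1 minus the complement sum, in log space);
* linear-kernel SVM classification of tumor vs normal with stratified
  k-fold cross-validation, random oversampling of the minority class inside
  each training fold, and ROC/AUC from pooled out-of-fold decision scores;
* single-linkage hierarchical clustering with cityblock (L1) distance, cut
  at two clusters, scored by how many true normal samples land in the
  majority-normal cluster;
* per-gene two-sided Welch t-tests between the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln, logsumexp
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import DataError, ExpressionMatrix, SampleGroups, NORMAL, TUMOR

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hypergeometric enrichment

@dataclass
class EnrichmentResult:
    N: int  # universe size (total genes)
    M: int  # known reference genes in the universe
    n: int  # predicted genes
    x: int  # overlap
    p: float


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, M: int, n: int, x: int) -> float:
    """P(X >= x) for a hypergeometric draw of n from N with M successes.

    Computed as 1 minus the sum over k < x of C(M,k) C(N-M,n-k) / C(N,n),
    accumulated in log space; for a large complement the tail is summed
    directly instead, so tiny probabilities keep full relative precision.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise DataError("need 0 <= M <= N and 0 <= n <= N")
    if x < 0:
        raise DataError("x must be >= 0")
    lo = max(0, n - (N - M))
    hi = min(M, n)
    if x > hi:
        raise DataError(f"x = {x} exceeds min(M, n) = {hi}: infeasible overlap")
    if x <= lo:
        return 1.0

    def _terms(ks: np.ndarray) -> np.ndarray:
        return (
            _log_comb(M, ks) + np.array([_log_comb(N - M, n - k) for k in ks])
            - _log_comb(N, n)
        )

    upper_ks = np.arange(x, hi + 1)
    lower_ks = np.arange(lo, x)
    log_upper = logsumexp(_terms(upper_ks))
    if log_upper < np.log(0.5):
        # tail is small: direct summation keeps relative precision
        return float(np.exp(log_upper))
    return float(max(0.0, -np.expm1(logsumexp(_terms(lower_ks)))))


def enrichment_test(
    predicted: set[str], reference: set[str], universe: set[str]
) -> EnrichmentResult:
    """Enrichment of predicted genes in a reference list over a gene universe."""
    pred = predicted & universe
    ref = reference & universe
    x = len(pred & ref)
    res = EnrichmentResult(
        N=len(universe), M=len(ref), n=len(pred), x=x,
        p=hypergeom_tail(len(universe), len(ref), len(pred), x),
    )
    log.info("enrichment: N=%d M=%d n=%d x=%d p=%.4g", res.N, res.M, res.n, res.x, res.p)
    return res


# ---------------------------------------------------------------------------
# supervised validation

@dataclass
class ClassificationReport:
    auc: float
    fold_count: int
    roc_points: list[tuple[float, float]]
    oversampled: bool
    scores: np.ndarray = field(repr=False, default=None)
    y_true: np.ndarray = field(repr=False, default=None)


def _oversample(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Balance classes by resampling the minority training rows with replacement."""
    classes, counts = np.unique(y[idx], return_counts=True)
    target = counts.max()
    out = []
    for cls, cnt in zip(classes, counts):
        members = idx[y[idx] == cls]
        out.append(members)
        if cnt < target:
            out.append(rng.choice(members, size=target - cnt, replace=True))
    merged = np.concatenate(out)
    rng.shuffle(merged)
    return merged


def classify_cv(
    expr: ExpressionMatrix,
    gene_subset: set[str],
    groups: SampleGroups,
    folds: int = 5,
    oversample: bool = True,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold SVM (linear kernel) on the gene-subset features."""
    genes = sorted(gene_subset)
    missing = [g for g in genes if g not in set(expr.genes)]
    if missing:
        raise DataError(f"gene subset not in expression matrix: {missing[:5]}")
    groups.require_both_groups(expr.samples)
    X = expr.values.loc[genes].to_numpy(dtype=float).T  # samples x genes
    y = np.array([1 if groups.group(s) == TUMOR else 0 for s in expr.samples])
    if min(np.bincount(y)) < folds:
        raise DataError(
            f"minority class has fewer samples than folds={folds}; reduce folds"
        )
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for train, test in skf.split(X, y):
        fit_idx = _oversample(train, y, rng) if oversample else train
        clf = SVC(kernel="linear")
        clf.fit(X[fit_idx], y[fit_idx])
        scores[test] = clf.decision_function(X[test])
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    log.info("classification: AUC %.4f over %d folds", auc, folds)
    return ClassificationReport(
        auc=auc,
        fold_count=folds,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        oversampled=oversample,
        scores=scores,
        y_true=y,
    )


# ---------------------------------------------------------------------------
# unsupervised validation

@dataclass
class ClusteringReport:
    linkage: str
    metric: str
    cluster_assignment: dict[str, int]
    normal_cluster_recall: float


def cluster_samples(
    expr: ExpressionMatrix,
    gene_subset: set[str],
    groups: SampleGroups,
) -> ClusteringReport:
    """Single-linkage / cityblock 2-cluster cut; recall of normal samples.

    The cluster holding the larger number of true normal samples is taken as
    the normal cluster; recall is the fraction of all normals placed there.
    """
    genes = sorted(gene_subset)
    if not genes:
        raise DataError("gene subset is empty")
    samples = expr.samples
    if len(samples) < 2:
        raise DataError("need at least 2 samples to cluster")
    groups.require_covers(samples)
    X = expr.values.loc[genes].to_numpy(dtype=float).T
    if np.unique(X, axis=0).shape[0] == 1:
        log.warning("all sample vectors identical; clustering is degenerate")
    Z = linkage(X, method="single", metric="cityblock")
    labels = fcluster(Z, t=2, criterion="maxclust")
    normals = np.array([groups.group(s) == NORMAL for s in samples])
    n_normal = int(normals.sum())
    if n_normal == 0:
        raise DataError("no normal samples to evaluate clustering against")
    counts = {c: int((normals & (labels == c)).sum()) for c in np.unique(labels)}
    normal_cluster = max(sorted(counts), key=lambda c: counts[c])
    recall = counts[normal_cluster] / n_normal
    log.info("clustering: normal-cluster recall %.3f", recall)
    return ClusteringReport(
        linkage="single",
        metric="cityblock",
        cluster_assignment={s: int(c) for s, c in zip(samples, labels)},
        normal_cluster_recall=float(recall),
    )


# ---------------------------------------------------------------------------
# per-gene differential expression

def per_gene_differential_test(
    expr: ExpressionMatrix,
    gene_subset: set[str],
    groups: SampleGroups,
) -> pd.DataFrame:
    """Two-sided Welch t-test per gene, with the direction of the shift."""
    tumor = [s for s in expr.samples if groups.group(s) == TUMOR]
    normal = [s for s in expr.samples if groups.group(s) == NORMAL]
    if len(tumor) < 2 or len(normal) < 2:
        raise DataError("both groups need at least 2 samples")
    rows = []
    for g in sorted(gene_subset):
        xt = expr.values.loc[g, tumor].to_numpy(dtype=float)
        xn = expr.values.loc[g, normal].to_numpy(dtype=float)
        t, p = stats.ttest_ind(xt, xn, equal_var=False)
        rows.append(
            {
                "gene": g,
                "t": float(t),
                "p": float(p),
                "direction": "up_in_tumor" if xt.mean() > xn.mean() else "down_in_tumor",
            }
        )
    return pd.DataFrame(rows)
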