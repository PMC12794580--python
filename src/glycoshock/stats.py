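"""Nonparametric statistics, rank-based ROC and average-linkage clustering.

Group comparisons between survivors and nonsurvivors use Mann-Whitney U
tests (unpaired, unequal group sizes, no normality assumption); paired
within-spectrum or within-patient comparisons use the Wilcoxon signed-rank
test. Single-feature discriminative ability is summarised by the ROC AUC
computed by concordant-pair counting, which coincides with the normalised
Mann-Whitney U statistic. Unsupervised structure in log2-transformed glycome
matrices is explored with Euclidean average-linkage agglomerative clustering.

Method-selection conventions (documented so p-values are reproducible):
Mann-Whitney uses the exact null when the pooled sample has at most 12
observations and no ties, otherwise the normal approximation with tie and
continuity corrections; Wilcoxon uses the exact null for up to 20 nonzero
differences without ties, zero differences dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "TestResult",
    "RocResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "roc_auc",
    "hclust_average",
    "log2_preprocess",
    "benjamini_hochberg",
]

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str


@dataclass(frozen=True)
class RocResult:
    auc: float
    curve: List[Tuple[float, float]]  # (false-positive rate, true-positive rate)


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {sorted(_ALTERNATIVES)}, got {alternative!r}"
        )
    return _ALTERNATIVES[alternative]


def mann_whitney_u(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann-Whitney U test; statistic is U of the first sample with mid-rank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires both groups nonempty")
    alt = _check_alternative(alternative)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        method=f"mann_whitney_u/{method}",
    )


def wilcoxon_signed_rank(x, y=None, alternative: str = "two_sided") -> TestResult:
    """Wilcoxon signed-rank test on paired data (or on precomputed differences).

    Zero differences are dropped before ranking; all-zero input is an error.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    alt = _check_alternative(alternative)
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 20 and not has_ties) else "approx"
    res = _sps.wilcoxon(d, alternative=alt, method=method, correction=(method == "approx"))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        method=f"wilcoxon_signed_rank/{method}",
    )


def roc_auc(scores, labels) -> RocResult:
    """Univariate ROC using the raw feature as score; positive label = 1.

    AUC = (#concordant pairs + 1/2 #tied pairs) / (n_pos * n_neg), computed
    via mid-ranks so ties are handled exactly. The curve is the standard
    threshold sweep from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0 = negative, 1 = positive)")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = _sps.rankdata(scores)  # mid-ranks
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    curve = list(zip(fpr.tolist(), tpr.tolist()))
    if curve[0] != (0.0, 0.0):
        curve.insert(0, (0.0, 0.0))
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    return RocResult(auc=float(auc), curve=curve)


def hclust_average(matrix, metric: str = "euclidean") -> np.ndarray:
    """Agglomerative clustering with average linkage (UPGMA).

    Implements the Lance-Williams update d(new,k) = (n_i d(i,k) + n_j d(j,k))
    / (n_i + n_j) with a deterministic tie-break: among minimal-distance
    cluster pairs, merge the one with the smallest (i, j) cluster-index pair
    (original rows 0..n-1, merged clusters n, n+1, ...). Returns a linkage
    matrix of (n-1) rows [i, j, distance, size], compatible with
    scipy.cluster.hierarchy consumers.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("clustering requires a 2-D matrix with >= 2 rows")
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-finite value at row {r}, column {c}")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    n = X.shape[0]
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(X[i] - X[j]))
    active = {i: 1 for i in range(n)}  # cluster id -> size
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j) = min(dist, key=lambda p: (dist[p], p))
        d_ij = dist.pop((i, j))
        n_i, n_j = active.pop(i), active.pop(j)
        new_dist = {}
        for k in active:
            a = dist.pop((min(i, k), max(i, k)))
            b = dist.pop((min(j, k), max(j, k)))
            new_dist[(k, next_id)] = (n_i * a + n_j * b) / (n_i + n_j)
        dist.update(new_dist)
        active[next_id] = n_i + n_j
        merges.append([float(i), float(j), d_ij, float(n_i + n_j)])
        next_id += 1
    return np.asarray(merges)


def log2_preprocess(matrix, floor: Optional[float] = None):
    """Elementwise log2(value + floor) for clustering/heat-map input.

    ``floor`` defaults to half the smallest nonzero value of the matrix, so
    zeros map to a finite value below every observed abundance.
    """
    import pandas as pd

    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("log2_preprocess requires nonnegative input")
    if floor is None:
        nonzero = X[X > 0]
        if nonzero.size == 0:
            raise ValueError("all-zero matrix: provide an explicit floor")
        floor = float(nonzero.min()) / 2.0
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    out = np.log2(X + floor)
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional FDR adjustment (off by default throughout the package)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
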