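"""Shared evaluation statistics.

Depth-normalised pseudobulk profiles, the normalised Wilcoxon signed-rank
("paired-rank") statistic used both for sex-bias scoring and for
differential-accessibility direction, the local inverse Simpson's index
(LISI) for mixing, AUROC, positive-proportion-normalised AUPR, and paired
one-sided Wilcoxon comparisons against baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from sklearn import metrics as skm


@dataclass
class MetricResult:
    name: str
    value: float
    n: int
    extras: dict = field(default_factory=dict)


def pseudobulk(cells) -> np.ndarray:
    """Depth-normalise every cell to unit total, then average across cells.

    Zero-depth cells are excluded (with a warning); the result sums to 1 and
    is invariant to per-cell depth rescaling.
    """
    if sparse.issparse(cells):
        cells = np.asarray(cells.todense())
    cells = np.atleast_2d(np.asarray(cells, float))
    depth = cells.sum(axis=1)
    keep = depth > 0
    if not keep.any():
        raise ValueError("pseudobulk of all-zero cells is undefined")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-depth cell(s) "
                      "from pseudobulk")
        cells, depth = cells[keep], depth[keep]
    return (cells / depth[:, None]).mean(axis=0)


def paired_rank_statistic(a, b) -> float:
    """Normalised Wilcoxon signed-rank statistic W+ / (n(n+1)/2) in [0, 1].

    Computed on the paired differences ``a - b`` after dropping exact zeros
    (Wilcoxon convention) with midranks for tied magnitudes.  0.5 means no
    shift; 1 (0) means every ``a`` exceeds (falls below) its pair.  Returns
    0.5 when every difference is zero.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.5
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    return float(w_plus / (n * (n + 1) / 2.0))


def lisi(embeddings, labels, perplexity: float = 30.0) -> np.ndarray:
    """Per-cell local inverse Simpson's index of ``labels`` mixing.

    For each cell, neighbours are weighted with a Gaussian kernel whose
    bandwidth is calibrated so the weight entropy matches ``perplexity``
    (the construction of Korsunsky et al.); the score is the inverse Simpson
    index of the weighted label distribution, between 1 (one label locally)
    and the number of labels (perfect mixing).
    """
    X = np.asarray(embeddings, float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 2:
        raise ValueError("LISI requires at least two cells")
    uniq, lab_idx = np.unique(labels, return_inverse=True)
    if len(uniq) == 1:
        return np.ones(n)
    k = int(min(n - 1, max(5, 3 * perplexity)))
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist2, idx = dist[:, 1:] ** 2, idx[:, 1:]
    target = np.log(min(perplexity, k))
    scores = np.empty(n)
    for i in range(n):
        beta = _calibrate_beta(dist2[i], target)
        w = np.exp(-beta * (dist2[i] - dist2[i].min()))
        w /= w.sum()
        p = np.bincount(lab_idx[idx[i]], weights=w, minlength=len(uniq))
        scores[i] = 1.0 / np.sum(p**2)
    return scores


def _calibrate_beta(d2: np.ndarray, target_entropy: float,
                    tol: float = 1e-5, max_iter: int = 64) -> float:
    """Binary-search the Gaussian precision so weight entropy hits target."""
    beta, lo, hi = 1.0, 0.0, np.inf
    d2 = d2 - d2.min()
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        sw = w.sum()
        h = np.log(sw) + beta * (d2 * w).sum() / sw
        if abs(h - target_entropy) < tol:
            break
        if h > target_entropy:
            lo = beta
            beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = (lo + beta) / 2
    return beta


def auroc(scores, labels) -> float:
    """Rank-based AUROC with midrank tie handling."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(skm.roc_auc_score(labels, np.asarray(scores, float)))


def aupr_norm(scores, labels) -> float:
    """Positive-proportion-normalised area under the precision-recall curve.

    ``(AUPR - PP) / (1 - PP)`` where ``PP`` is the positive proportion: 0 is
    the expected value of a random ranking, 1 a perfect one (slightly
    negative values indicate worse-than-random rankings).
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPRnorm needs both classes present")
    pp = labels.mean()
    if pp >= 1.0:
        raise ValueError("AUPRnorm undefined when every label is positive")
    aupr = skm.average_precision_score(labels, np.asarray(scores, float))
    return float((aupr - pp) / (1.0 - pp))


def compare_paired(metric_a, metric_b, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value that ``metric_a`` > ``metric_b``.

    Identical inputs return p = 1 (no evidence of improvement).  Small
    samples (n < 5 non-zero pairs) use the exact permutation distribution
    with a warning.
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    d = a - b
    nz = np.count_nonzero(d)
    if nz == 0:
        return 1.0
    method = "auto"
    if nz < 5:
        warnings.warn(f"only {nz} non-zero pairs; using exact distribution")
        method = "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(a, b, alternative=alternative, method=method,
                             zero_method="wilcox")
    return float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)
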