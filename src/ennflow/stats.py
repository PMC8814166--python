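"""Shared statistical machinery.

Minimum-distance (nearest-centroid, Pearson-correlation) classification,
one-sided binomial tests against chance, Benjamini-Hochberg FDR, paired
t contrasts, and +1-corrected permutation p values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DecodingResult",
    "PermutationNull",
    "min_distance_classify",
    "binomial_pvalue",
    "fdr_bh",
    "paired_ttest_contrast",
    "permutation_pvalue",
]


@dataclass
class DecodingResult:
    accuracy: float
    n_test: int
    confusion: np.ndarray  # classes x classes counts, rows = true
    p_value: float | None = None
    method: str = "min_distance"

    def __post_init__(self) -> None:
        assert self.confusion.sum() == self.n_test


@dataclass
class PermutationNull:
    null_samples: np.ndarray
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null_samples = np.asarray(self.null_samples, dtype=np.float64)
        assert self.null_samples.shape == (self.n_perm,)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix with zero-variance rows giving r = 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    yn = np.linalg.norm(yc, axis=1)
    num = xc @ yc.T
    denom = np.outer(xn, yn)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def min_distance_classify(
    train_patterns: np.ndarray,
    train_labels: np.ndarray,
    test_patterns: np.ndarray,
    method: str = "min_distance",
    seed: int | None = None,
) -> np.ndarray:
    """Nearest-centroid classification with Pearson correlation similarity.

    Class centroids are the per-class means of the training patterns; each test
    pattern is assigned the class whose centroid it correlates with most.  Ties
    break to the lowest class index (deterministic).  A zero-variance pattern
    correlates 0 with everything.  ``method="logistic"`` instead fits a linear
    multinomial logistic model (the linear-decoder robustness comparison).
    """
    train_patterns = np.asarray(train_patterns, dtype=np.float64)
    test_patterns = np.asarray(test_patterns, dtype=np.float64)
    train_labels = np.asarray(train_labels)
    classes = np.unique(train_labels)
    if method == "logistic":
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(train_patterns, train_labels)
        return clf.predict(test_patterns)
    if method != "min_distance":
        raise ValueError(f"unknown classifier {method!r}")
    centroids = np.stack(
        [train_patterns[train_labels == c].mean(axis=0) for c in classes]
    )
    r = _safe_pearson(test_patterns, centroids)  # n_test x n_classes
    return classes[np.argmax(r, axis=1)]  # argmax takes the first (lowest) max


def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """One-sided P(X >= k) under Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(sps.binom.sf(k - 1, n, p0))


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (rejected mask, adjusted p)."""
    p_values = np.asarray(p_values, dtype=np.float64)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return rejected, p_adj


def paired_ttest_contrast(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t-test on (a - b), per feature (columns); pairs are rows."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("need equal shapes with >= 3 pairs")
    t, p = sps.ttest_rel(a, b, axis=0)
    # identical pairs give 0/0; define t = 0, p = 1
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return np.atleast_1d(t), np.atleast_1d(p)


def permutation_pvalue(observed: float, null: PermutationNull) -> float:
    """Nonparametric p with the +1 correction: (1 + #{null >= obs}) / (1 + n_perm)."""
    return float(
        (1 + np.sum(null.null_samples >= observed)) / (1 + null.n_perm)
    )
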