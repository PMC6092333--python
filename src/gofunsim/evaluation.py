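"""Benchmark statistics for comparing FS measures.

Pearson correlation against continuous reference scores, ROC/AUC against
binary labels, the Williams t-test for two dependent correlations
sharing one variable, a one-sided Wilcoxon signed-rank test with
continuity correction, and Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError


@dataclass
class PairedScores:
    """Scores of two measures plus a reference over the same pair list."""

    pairs: list[tuple[str, str]]
    fs: np.ndarray
    fs_star: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        self.fs = np.asarray(self.fs, dtype=float)
        self.fs_star = np.asarray(self.fs_star, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        n = len(self.pairs)
        if not (len(self.fs) == len(self.fs_star) == len(self.reference) == n):
            raise DegenerateInputError("paired score vectors differ in length")
        for v in (self.fs, self.fs_star, self.reference):
            if np.isnan(v).any():
                raise DegenerateInputError("paired scores contain NaN")


@dataclass
class WilliamsResult:
    """Outcome of the dependent-correlation t-test.

    ``r13``/``r23`` are the correlations of the two score vectors with
    the shared reference, ``r12`` the inter-score correlation, and ``K``
    the determinant of the 3x3 correlation matrix.
    """

    t: float
    df: int
    p: float
    r12: float
    r13: float
    r23: float
    K: float


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; errors on constant or too-short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise DegenerateInputError("correlation needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation of a constant vector is undefined")
    return float(stats.pearsonr(x, y).statistic)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC of the ROC curve; the Mann–Whitney probability of correct
    ranking with ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("ROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def williams_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    reference: Sequence[float],
    literal_variant: bool = False,
) -> WilliamsResult:
    """Williams t-test: is corr(A, ref) larger than corr(B, ref)?

    The two correlations share the reference variable and the scores are
    themselves correlated (r12), which this test accounts for:

        t(n-3) = (r13 - r23) * sqrt((n-1)(1+r12)) /
                 sqrt(2K(n-1)/(n-3) + ((r13+r23)/2)^2 (1-r12)^3)

    with K = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23.  The one-sided
    p-value comes from the t distribution with n-3 df; swapping A and B
    negates t.  ``literal_variant`` switches the denominator's mean-
    correlation term to a quarter-sum, an alternate printed form kept
    for comparison.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    ref = np.asarray(reference, dtype=float)
    n = len(a)
    if n < 4:
        raise DegenerateInputError("Williams test needs n >= 4")
    if np.array_equal(a, b):
        r13 = r23 = pearson(a, ref)
        r12 = 1.0
        k = 0.0
        return WilliamsResult(t=0.0, df=n - 3, p=0.5, r12=r12, r13=r13, r23=r23, K=k)
    r13 = pearson(a, ref)
    r23 = pearson(b, ref)
    r12 = pearson(a, b)
    k = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    mean_r = (r13 + r23) / (4.0 if literal_variant else 2.0)
    denom_sq = 2.0 * k * (n - 1) / (n - 3) + mean_r**2 * (1.0 - r12) ** 3
    if denom_sq <= 0:
        raise DegenerateInputError(
            "degenerate correlation structure (non-positive variance term)"
        )
    t = (r13 - r23) * np.sqrt((n - 1) * (1.0 + r12)) / np.sqrt(denom_sq)
    p = float(stats.t.sf(t, df=n - 3))
    return WilliamsResult(
        t=float(t), df=n - 3, p=p, r12=r12, r13=r13, r23=r23, K=k
    )


def wilcoxon_signed_rank_one_sided(
    before: Sequence[float], after: Sequence[float]
) -> float:
    """One-sided Wilcoxon signed-rank p-value for 'after > before'.

    Zero differences are dropped (Wilcoxon convention).  Exact
    enumeration of the sign-flip distribution for n <= 25 surviving
    pairs; the normal approximation with continuity correction above.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise DegenerateInputError("paired samples differ in length")
    diffs = after - before
    nz = diffs[diffs != 0]
    n = len(nz)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n > 25:
        res = stats.wilcoxon(
            after,
            before,
            alternative="greater",
            zero_method="wilcox",
            correction=True,
            method="approx",
        )
        return float(res.pvalue)
    # exact sign-flip distribution of W+; doubled midranks keep the DP
    # integral even with tied |differences|
    ranks2 = np.round(stats.rankdata(np.abs(nz)) * 2).astype(int)
    w_obs = int(ranks2[nz > 0].sum())
    counts = np.zeros(ranks2.sum() + 1)
    counts[0] = 1.0
    for r in ranks2:
        counts[r:] = counts[r:] + counts[:-r]
    return float(counts[w_obs:].sum() / 2.0**n)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise DegenerateInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
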