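"""Shared statistical primitives.

Multiple-testing adjustment (Benjamini-Hochberg, Bonferroni), the paired
Wilcoxon signed-rank test, the Mann-Whitney rank-sum test, and Fisher's exact
test, with explicit exact-vs-approximate switch points so that every result is
reproducible bit-for-bit across runs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

__all__ = [
    "adjust_pvalues",
    "bonferroni_threshold",
    "paired_signed_rank",
    "rank_sum",
    "fisher_exact",
]

#: exact signed-rank null is enumerated when the number of non-zero
#: differences is at most this many (2^25 outcomes via the count DP)
SIGNED_RANK_EXACT_MAX = 25

#: exact Mann-Whitney null is used when n*m is at most this
RANK_SUM_EXACT_MAX_NM = 400


def adjust_pvalues(p, method: str = "bh", m: int | None = None) -> np.ndarray:
    """Adjust p-values for multiple testing.

    Parameters
    ----------
    p : array-like of float
        Raw p-values, each in [0, 1].
    method : {"bh", "bonferroni"}
        "bh" applies the Benjamini-Hochberg step-up procedure (with enforced
        monotonicity); "bonferroni" returns ``min(1, p * m)``.
    m : int, optional
        Number of tests. Defaults to ``len(p)``; may exceed it when only a
        subset of an adjusted family is passed in.

    Returns
    -------
    numpy.ndarray
        Adjusted p-values, same order as the input, each in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    m = int(m)
    if m < p.size:
        raise ValueError(f"m ({m}) must be >= number of p-values ({p.size})")
    if p.size == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method != "bh":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance cutoff controlling FWER at ``alpha`` over ``m`` tests."""
    if m <= 0:
        raise ValueError("m must be positive")
    return alpha / m


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic by null enumeration.

    Counts, over all 2^n equiprobable sign assignments, the distribution of
    W+ via the classic subset-sum dynamic programme (integer ranks only).
    """
    r = np.rint(ranks).astype(int)
    total = int(r.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for ri in r:
        shifted = np.zeros_like(counts)
        shifted[ri:] = counts[: total + 1 - ri]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus))
    lower = counts[: w + 1].sum()
    upper = counts[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def paired_signed_rank(x, y, zero_method: str = "drop") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (two-sided).

    Differences ``y - x`` equal to zero are dropped before ranking (the
    classic Wilcoxon convention; set ``zero_method="pratt"`` to keep them in
    the ranking as in Pratt's variant). The null distribution is enumerated
    exactly when there are at most 25 non-zero, untied differences; otherwise
    a normal approximation with tie/zero corrections is used.

    Returns ``(W+, p)`` where ``W+`` is the sum of ranks of positive
    differences. All-zero differences give ``p = 1`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= SIGNED_RANK_EXACT_MAX and not has_ties:
        ranks = sps.rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
        return w_plus, _signed_rank_exact_p(ranks, w_plus)
    scipy_zero = {"drop": "wilcox", "pratt": "pratt"}.get(zero_method)
    if scipy_zero is None:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on ties under approx
        res = sps.wilcoxon(
            y, x, zero_method=scipy_zero, alternative="two-sided", method="approx"
        )
    # scipy reports min(W+, W-); recover W+ for a stable statistic definition
    dd = d if zero_method == "pratt" else nz
    ranks = sps.rankdata(np.abs(dd))
    if zero_method == "pratt":
        ranks = np.where(dd == 0, 0.0, ranks)
    w_plus = float(ranks[dd > 0].sum())
    return w_plus, float(res.pvalue)


def rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact null when ``len(a) * len(b) <= 400`` and there are no cross-group
    ties; otherwise the normal approximation with midranks and tie
    correction. Returns ``(U, p)`` with U the Mann-Whitney statistic of the
    first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= RANK_SUM_EXACT_MAX_NM and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table, alternative: str = "two_sided") -> float:
    """Fisher's exact test on a 2x2 contingency table of non-negative counts.

    ``alternative`` is ``"two_sided"`` or ``"greater"`` (odds ratio > 1 for
    the [0,0] cell).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValueError("table cells must be non-negative integers")
    alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = sps.fisher_exact(t.astype(int), alternative=alt)
    return float(p)
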