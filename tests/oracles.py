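"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — full enumeration or per-pair model
fits — and shares no code with the package implementations it checks.
"""

from itertools import combinations, product

import numpy as np
from scipy import stats as sps
from scipy.special import comb


def bh_stepup(p, m=None):
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if m is None:
        m = n
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def signed_rank_exact(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    lower = (ws <= w_obs).mean()
    upper = (ws >= w_obs).mean()
    return w_obs, min(1.0, 2.0 * min(lower, upper))


def rank_sum_exact(a, b):
    """Two-sided Mann-Whitney p by enumerating all rank splits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = a.size
    idx = range(pooled.size)
    r_obs = ranks[:na].sum()
    u_obs = r_obs - na * (na + 1) / 2.0
    us = []
    for chosen in combinations(idx, na):
        r = ranks[list(chosen)].sum()
        us.append(r - na * (na + 1) / 2.0)
    us = np.asarray(us)
    mean_u = us.mean()
    dev = abs(u_obs - mean_u)
    p = (np.abs(us - mean_u) >= dev - 1e-12).mean()
    return u_obs, min(1.0, p)


def fisher_greater(table):
    """One-sided (greater) Fisher p by hypergeometric tail enumeration."""
    (a, b), (c, d) = table
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        p += (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )
    return p


def ols_per_pair(y, d, covariates):
    """(beta, t, p, r2_partial) of dosage in OLS with intercept + covariates."""
    n = y.size
    X = np.column_stack([np.ones(n), covariates, d])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[-1, -1])
    t = beta[-1] / se
    p = 2 * sps.t.sf(abs(t), df)
    # partial R^2 of the dosage term
    X0 = X[:, :-1]
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = np.sum((y - X0 @ b0) ** 2)
    rss1 = resid @ resid
    r2p = (rss0 - rss1) / rss0
    return beta[-1], t, p, df, r2p


def diff_ols(expr_control, expr_heat, dosage, covariates):
    """Within-genotype contrast oracle for the balanced paired design.

    Regress (heat - control) on intercept + covariates + dosage; the dosage
    coefficient equals the mixed-model interaction, with df = n - p.
    """
    diff = np.asarray(expr_heat) - np.asarray(expr_control)
    n = diff.size
    X = np.column_stack([np.ones(n), covariates, dosage])
    beta, *_ = np.linalg.lstsq(X, diff, rcond=None)
    resid = diff - X @ beta
    df = n - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
    t = beta[-1] / se
    return beta[-1], se, df, t, 2 * sps.t.sf(abs(t), df)


def ld_prune_bruteforce(dosage, maf, chrom, window, step, r2_max):
    """Literal re-implementation of the greedy windowed pruning rule.

    Written independently of the package: recomputes r^2 from scratch per
    window and applies "first violating pair in order, drop lower MAF (tie:
    later)" until stable.
    """
    m = dosage.shape[1]
    keep = np.ones(m, dtype=bool)
    for ch in dict.fromkeys(chrom):  # preserve order
        cidx = [j for j in range(m) if chrom[j] == ch]
        start = 0
        while True:
            widx = cidx[start : start + window]
            if len(widx) >= 2:
                while True:
                    alive = [j for j in widx if keep[j]]
                    violated = None
                    for x in range(len(alive)):
                        for yv in range(x + 1, len(alive)):
                            i, j = alive[x], alive[yv]
                            r = np.corrcoef(dosage[:, i], dosage[:, j])[0, 1]
                            if r * r > r2_max:
                                violated = (i, j)
                                break
                        if violated:
                            break
                    if not violated:
                        break
                    i, j = violated
                    if maf[i] < maf[j]:
                        keep[i] = False
                    else:
                        keep[j] = False
            if start + window >= len(cidx):
                break
            start += step
    return keep
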