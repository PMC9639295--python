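"""Random-intercept linear mixed model with Satterthwaite tests.

Implements the model

    y = X beta + Z u + e,   u ~ N(0, sigma_g^2 I_q),   e ~ N(0, sigma_e^2 I_n)

with one random intercept per group (here: per genotype), fitted by
restricted maximum likelihood. The variance ratio ``lambda = sigma_g^2 /
sigma_e^2`` is profiled; with equal group sizes k the marginal precision is
``V^{-1} = sigma_e^{-2} (I - w J)`` per group with ``w = lambda / (1 + k
lambda)``, so the profiled REML criterion depends on lambda only through the
generalized eigenvalues of the group-sum Gram matrix against ``X'X``. Those
are computed once per fit, after which each criterion evaluation is O(p) and
the 1-D bounded search is essentially free.

Fixed-effect coefficients are tested with t statistics whose denominator
degrees of freedom come from the Satterthwaite approximation

    df = 2 (c' C c)^2 / (g' A g)

where ``C = (X' V^{-1} X)^{-1}``, ``g`` is the gradient of ``c' C c`` with
respect to the variance components ``theta = (sigma_g^2, sigma_e^2)`` and
``A`` is the inverse expected REML information, ``A^{-1}_{jk} =
tr(P V_j P V_k) / 2`` with ``P = V^{-1} - V^{-1} X C X' V^{-1}``. In a
complete paired two-condition design with condition-invariant covariates
this reproduces ordinary least squares on within-genotype differences
exactly, including its residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = ["RandomInterceptLMM", "ContrastTest"]


@dataclass
class ContrastTest:
    """t-test of one fixed-effect coefficient with Satterthwaite df."""

    estimate: float
    se: float
    df: float
    tvalue: float
    pvalue: float


class RandomInterceptLMM:
    """REML fit of a single-random-intercept mixed model.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design (include the intercept column yourself).
    groups : (n,) group labels (any dtype); one random intercept per label.
        All groups must be the same size (complete designs; drop incomplete
        groups upstream).

    Attributes (populated by :meth:`fit`)
    -------------------------------------
    beta : fixed-effect estimates (aliased columns carry NaN).
    sigma2_g, sigma2_e : REML variance components (sigma2_g may be 0).
    kept : indices of non-aliased design columns.
    """

    def __init__(self, y, X, groups):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, p) matching y")
        _, self._gidx = np.unique(np.asarray(groups), return_inverse=True)
        self._q = int(self._gidx.max()) + 1
        ksz = np.bincount(self._gidx)
        if ksz.min() != ksz.max():
            raise ValueError("all groups must have equal size")
        self._k = int(ksz[0])
        self.beta = None
        self.sigma2_g = np.nan
        self.sigma2_e = np.nan
        self.kept = None

    # -- internals -----------------------------------------------------------

    def _drop_aliased(self) -> np.ndarray:
        """Greedy left-to-right selection of a full-rank column subset."""
        X = self.X
        norms = np.linalg.norm(X, axis=0)
        norms = np.where(norms == 0, 1.0, norms)
        Q = np.zeros((X.shape[0], 0))
        kept = []
        for j in range(X.shape[1]):
            v = X[:, j] / norms[j]
            resid = v - Q @ (Q.T @ v)
            nr = np.linalg.norm(resid)
            if nr > 1e-8:
                Q = np.column_stack([Q, resid / nr])
                kept.append(j)
        if len(kept) < X.shape[1]:
            warnings.warn(
                f"dropping {X.shape[1] - len(kept)} aliased design column(s)",
                stacklevel=3,
            )
        return np.array(kept, dtype=int)

    # -- public API ----------------------------------------------------------

    def fit(self) -> "RandomInterceptLMM":
        self.kept = self._drop_aliased()
        Xk = self.X[:, self.kept]
        n, p = Xk.shape
        if n - p < 1:
            raise ValueError("no residual degrees of freedom")
        gidx, q, k = self._gidx, self._q, self._k

        S = np.zeros((q, p))
        np.add.at(S, gidx, Xk)
        t = np.bincount(gidx, weights=self.y, minlength=q)
        XtX = Xk.T @ Xk
        StS = S.T @ S
        Xty = Xk.T @ self.y
        Sty = S.T @ t
        yty = float(self.y @ self.y)
        ttt = float(t @ t)

        # simultaneous diagonalization of (StS, XtX)
        R = np.linalg.cholesky(XtX + 0.0)
        Rinv = np.linalg.inv(R)
        T = Rinv @ StS @ Rinv.T
        phi, U = np.linalg.eigh((T + T.T) / 2.0)
        phi = np.clip(phi, 0.0, k)
        u1 = U.T @ (Rinv @ Xty)
        u2 = U.T @ (Rinv @ Sty)

        def crit(lam: float) -> float:
            w = lam / (1.0 + k * lam)
            one_minus = 1.0 - w * phi
            bt = u1 - w * u2
            quad = float((bt * bt / one_minus).sum())
            r = yty - w * ttt - quad
            if r <= 0:
                return np.inf
            return (
                (n - p) * np.log(r)
                + q * np.log1p(k * lam)
                + float(np.log(one_minus).sum())
            )

        res = optimize.minimize_scalar(
            lambda z: crit(np.exp(z)),
            bounds=(-18.0, 14.0),
            method="bounded",
            options={"xatol": 1e-9},
        )
        lam = float(np.exp(res.x))
        if crit(0.0) <= crit(lam):  # boundary sigma_g^2 = 0 wins
            lam = 0.0

        w = lam / (1.0 + k * lam)
        M = XtX - w * StS
        b = Xty - w * Sty
        beta = np.linalg.solve(M, b)
        r = yty - w * ttt - float(b @ beta)
        self.sigma2_e = r / (n - p)
        self.sigma2_g = lam * self.sigma2_e
        full = np.full(self.X.shape[1], np.nan)
        full[self.kept] = beta
        self.beta = full
        self._Xk = Xk
        return self

    def test(self, index: int) -> ContrastTest:
        """Satterthwaite t-test of the coefficient at design column ``index``."""
        if self.beta is None:
            raise RuntimeError("call fit() first")
        if index not in set(self.kept.tolist()):
            raise ValueError(f"design column {index} was dropped as aliased")
        kpos = int(np.where(self.kept == index)[0][0])
        Xk = self._Xk
        n, p = Xk.shape
        gidx, q = self._gidx, self._q
        s2g, s2e = self.sigma2_g, self.sigma2_e

        # dense V^{-1}: per-group block (s2e I + s2g J)^{-1}
        w = s2g / (s2e * (s2e + self._k * s2g))
        Vi = np.where(gidx[:, None] == gidx[None, :], -w, 0.0)
        np.fill_diagonal(Vi, 1.0 / s2e - w)

        B = Vi @ Xk
        C = np.linalg.inv(Xk.T @ B)
        P = Vi - B @ C @ B.T

        v_c = float(C[kpos, kpos])
        a = B @ C[:, kpos]  # = V^{-1} X C c
        g_e = float(a @ a)
        za = np.bincount(gidx, weights=a, minlength=q)
        g_g = float(za @ za)

        M = np.zeros((q, n))
        np.add.at(M, gidx, P)  # M = Z' P, i.e. (P Z)'
        i_ee = 0.5 * float((P * P).sum())
        i_eg = 0.5 * float((M * M).sum())
        ZM = np.zeros((q, q))
        np.add.at(ZM, gidx, M.T)
        i_gg = 0.5 * float((ZM * ZM).sum())
        A = np.linalg.pinv(np.array([[i_gg, i_eg], [i_eg, i_ee]]))
        g = np.array([g_g, g_e])
        denom = float(g @ A @ g)
        df = 2.0 * v_c**2 / denom if denom > 0 else float(n - p)
        est = float(self.beta[index])
        se = float(np.sqrt(v_c))
        tval = est / se
        pval = float(2.0 * sps.t.sf(abs(tval), df))
        return ContrastTest(est, se, df, tval, pval)
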