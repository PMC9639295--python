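"""Expression normalization, expressed-gene sets, paired differential tests.

The paired design here is one control and one heat-stress RNA-seq library
per genotype. Counts are normalized to CPM (counts per million), gene
expression is compared between conditions with a paired Wilcoxon signed-rank
test, and per-genotype heat/control responses use log2 ratios of CPM with a
+1 pseudocount throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_pvalues, paired_signed_rank

__all__ = [
    "ExpressionPair",
    "ExpressedSets",
    "cpm_normalize",
    "expressed_gene_sets",
    "paired_de",
    "consistent_upregulation",
    "inverse_normal_transform",
    "infer_hidden_factors",
    "transcriptome_plasticity",
]


def cpm_normalize(counts, mode: str = "total_count"):
    """Normalize a genes x samples count matrix to counts per million.

    ``total_count`` divides each column by its sum; ``median_of_ratios``
    first computes per-sample size factors as the median ratio to the
    per-gene geometric mean (over genes expressed in all samples), then
    applies one global constant so the median effective library equals 1e6.
    Accepts and returns either a DataFrame or an ndarray.
    """
    is_df = isinstance(counts, pd.DataFrame)
    M = counts.to_numpy(dtype=float) if is_df else np.asarray(counts, dtype=float)
    colsums = M.sum(axis=0)
    if np.any(colsums <= 0):
        bad = np.flatnonzero(colsums <= 0)
        names = (
            [counts.columns[i] for i in bad] if is_df else bad.tolist()
        )
        raise ValueError(f"zero library size for sample(s) {names}")
    if mode == "total_count":
        out = M / colsums * 1e6
    elif mode == "median_of_ratios":
        pos = (M > 0).all(axis=1)
        if not pos.any():
            raise ValueError("no gene expressed in every sample")
        loggeo = np.log(M[pos]).mean(axis=1)
        sf = np.exp(np.median(np.log(M[pos]) - loggeo[:, None], axis=0))
        adj = M / sf
        out = adj * (1e6 / np.median(adj.sum(axis=0)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if is_df:
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


@dataclass
class ExpressionPair:
    """Paired control/heat count and CPM matrices over the same genotypes."""

    genes: list
    samples: list
    counts_control: np.ndarray
    counts_heat: np.ndarray
    cpm_control: np.ndarray = field(default=None)
    cpm_heat: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts_control = np.asarray(self.counts_control, dtype=float)
        self.counts_heat = np.asarray(self.counts_heat, dtype=float)
        shape = (len(self.genes), len(self.samples))
        if self.counts_control.shape != shape or self.counts_heat.shape != shape:
            raise ValueError("count matrices must be genes x samples")
        if self.cpm_control is None:
            self.cpm_control = cpm_normalize(self.counts_control)
        if self.cpm_heat is None:
            self.cpm_heat = cpm_normalize(self.counts_heat)

    @property
    def libsizes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "control": self.counts_control.sum(axis=0),
                "heat": self.counts_heat.sum(axis=0),
            },
            index=self.samples,
        )

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def log2_ratio(self, pseudocount: float = 1.0) -> np.ndarray:
        """Per-genotype log2((CPM_heat + pc) / (CPM_control + pc))."""
        return np.log2(
            (self.cpm_heat + pseudocount) / (self.cpm_control + pseudocount)
        )


@dataclass
class ExpressedSets:
    control: set
    heat: set
    common: set
    control_only: set
    heat_only: set


def expressed_gene_sets(
    pair: ExpressionPair, cpm_min: float = 1.0, frac_min: float = 0.10
) -> ExpressedSets:
    """Expressed genes per condition: CPM strictly above ``cpm_min`` in at
    least ``ceil(frac_min * n_samples)`` genotypes."""
    need = int(np.ceil(frac_min * len(pair.samples)))
    genes = np.asarray(pair.genes)
    in_c = (pair.cpm_control > cpm_min).sum(axis=1) >= need
    in_h = (pair.cpm_heat > cpm_min).sum(axis=1) >= need
    sc, sh = set(genes[in_c]), set(genes[in_h])
    return ExpressedSets(sc, sh, sc & sh, sc - sh, sh - sc)


def paired_de(
    pair: ExpressionPair,
    genes=None,
    p_adj_max: float = 0.01,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Paired Wilcoxon differential expression between conditions.

    Tests CPM per gene across genotypes, BH-adjusts over the tested genes,
    and calls up/down with ``|log2fc_median| > lfc_min`` where log2fc_median
    uses condition-median CPM with a +1 pseudocount. Also reports the
    coefficient of variation of heat CPM (for response-vs-variability plots).
    """
    if len(pair.samples) < 6:
        warnings.warn("fewer than 6 genotypes: paired test has low power")
    gene_ids = list(pair.genes) if genes is None else list(genes)
    idx = pair.gene_index(gene_ids)
    rows = []
    for g, i in zip(gene_ids, idx):
        c = pair.cpm_control[i]
        h = pair.cpm_heat[i]
        _, p = paired_signed_rank(c, h)
        med_c, med_h = np.median(c), np.median(h)
        lfc = np.log2((med_h + 1.0) / (med_c + 1.0))
        mean_h = h.mean()
        cv_h = h.std(ddof=1) / mean_h if mean_h > 0 else np.nan
        rows.append((g, lfc, cv_h, p))
    out = pd.DataFrame(rows, columns=["gene_id", "log2fc_median", "cv_heat", "de_p"])
    out["de_p_adj"] = adjust_pvalues(out["de_p"].to_numpy(), method="bh")
    sig = out["de_p_adj"] < p_adj_max
    out["up_DEG"] = sig & (out["log2fc_median"] > lfc_min)
    out["down_DEG"] = sig & (out["log2fc_median"] < -lfc_min)
    return out


def consistent_upregulation(
    pair: ExpressionPair,
    genes=None,
    quantile_q: float = 0.90,
    pseudocount: float = 1.0,
) -> set:
    """Genes whose per-genotype log2 heat/control ratio has median > 0 and
    ``quantile_q`` quantile > 0 (linear-interpolation quantiles)."""
    r = pair.log2_ratio(pseudocount)
    med = np.median(r, axis=1)
    q = np.quantile(r, quantile_q, axis=1, method="linear")
    genes_arr = np.asarray(pair.genes)
    mask = (med > 0) & (q > 0)
    result = set(genes_arr[mask])
    if genes is not None:
        result &= set(genes)
    return result


def inverse_normal_transform(x) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Maps values to ``Phi^-1((rank - 3/8) / (n + 1/4))`` using average ranks
    for ties; a constant vector maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: inverse normal transform is all zeros")
        return np.zeros_like(x)
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def infer_hidden_factors(
    expr, k: int, known_covariates=None
) -> np.ndarray:
    """Hidden expression factors as principal components of residual expression.

    ``expr`` is genes x samples (normalized). Each gene is standardized,
    the sample x gene matrix is residualized on the known covariates (with
    intercept), and the top-``k`` sample scores are returned with a
    deterministic sign convention (largest-magnitude gene loading positive).
    A probabilistic-factor surrogate: deterministic and covariate-aware.
    """
    E = np.asarray(expr, dtype=float)
    n = E.shape[1]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if k == 0:
        return np.zeros((n, 0))
    mu = E.mean(axis=1, keepdims=True)
    sd = E.std(axis=1, keepdims=True, ddof=0)
    ok = sd[:, 0] > 0
    Y = ((E[ok] - mu[ok]) / sd[ok]).T  # samples x genes
    C = np.ones((n, 1))
    if known_covariates is not None and np.size(known_covariates):
        C = np.column_stack([C, np.asarray(known_covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    Y = Y - Q @ (Q.T @ Y)
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return (U * s * flip)[:, :k]


def screen_genetic_factors(factors: np.ndarray, dosage: np.ndarray,
                           r2_max: float = 0.25) -> np.ndarray:
    """Drop inferred factors that are mostly explained by a single variant.

    Hidden-factor correction absorbs any strong shared axis of expression —
    including the signature of a real trans-regulator, which would erase the
    very hotspots a scan is meant to find. A technical or environmental
    factor should never be largely determined by one genotype, so any factor
    whose best single-variant R^2 exceeds ``r2_max`` is treated as genetic
    signal and removed. With ~100 samples the chance maximum R^2 over even
    10^4 variants stays below ~0.15, well under the default threshold.

    ``dosage`` is the (samples x variants) matrix the factors' samples map
    onto; for factors inferred from a condition-stacked expression matrix,
    pass the dosage matrix stacked the same way.
    """
    if factors.shape[1] == 0:
        return factors
    D = dosage - np.nanmean(dosage, axis=0)
    D = np.nan_to_num(D)
    dn = np.sqrt((D * D).sum(axis=0))
    dn[dn == 0] = np.inf
    F = factors - factors.mean(axis=0)
    fn = np.sqrt((F * F).sum(axis=0))
    fn[fn == 0] = np.inf
    r2 = ((F / fn).T @ (D / dn)) ** 2
    keep = r2.max(axis=1) <= r2_max
    return factors[:, keep]


def transcriptome_plasticity(expr_control, expr_heat, samples=None) -> pd.DataFrame:
    """Per-genotype transcriptome shift |PC1_heat - PC1_control| in tertiles.

    A PCA over the pooled sample-condition observations (both conditions
    stacked, genes as features) yields PC1 scores; the absolute
    within-genotype difference is the plasticity score, classified into
    equal-size tertiles small/medium/large (ties resolve toward the lower
    class by sample order).
    """
    Ec = np.asarray(expr_control, dtype=float)
    Eh = np.asarray(expr_heat, dtype=float)
    if Ec.shape != Eh.shape:
        raise ValueError("conditions must cover the same genes and genotypes")
    n = Ec.shape[1]
    M = np.vstack([Ec.T, Eh.T])  # 2n observations x genes
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    pc1 = U[:, 0] * s[0]
    delta = np.abs(pc1[n:] - pc1[:n])
    order = np.argsort(delta, kind="stable")
    lab = np.empty(n, dtype=object)
    cut1, cut2 = (n + 2) // 3, (n + 2) // 3 + (n + 1) // 3
    lab[order[:cut1]] = "small"
    lab[order[cut1:cut2]] = "medium"
    lab[order[cut2:]] = "large"
    idx = samples if samples is not None else list(range(n))
    return pd.DataFrame({"sample": idx, "delta_pc1": delta, "plasticity_class": lab})
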