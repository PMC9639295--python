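"""Genotype containers, variant QC, LD pruning, population-structure PCs.

Dosages are alt-allele counts in {0, 1, 2} (NaN = missing call). The panels
this package targets are inbred lines, so dosages are near-homozygous
({0, 2} with a small residual-heterozygosity leak), but nothing here assumes
it: heterozygous-rate and MAF filters are applied explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GenotypeMatrix",
    "VariantStats",
    "variant_stats",
    "variant_stats_and_filter",
    "pairwise_r2",
    "ld_prune",
    "compute_pcs",
    "PCAResult",
    "select_diverse_subset",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "is_indel"]


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with variant metadata.

    Parameters
    ----------
    samples : unique sample identifiers (length n).
    variants : DataFrame with columns id, chrom, pos (1-based), ref, alt,
        is_indel, sorted by (chrom, pos).
    dosage : float array (n_samples, n_variants) with values in {0, 1, 2}
        or NaN for missing calls.
    """

    samples: list
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variants missing columns {sorted(missing_cols)}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape must be (n_samples, n_variants)")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        order = self.variants.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, self.variants.index.to_numpy()):
            self.variants = self.variants.loc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]
        else:
            self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) == 0:
            raise KeyError(variant_id)
        return self.dosage[:, j[0]]

    def subset_variants(self, keep: Sequence) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {v: i for i, v in enumerate(self.variants["id"])}
            idx = np.array([pos[v] for v in keep], dtype=int)
            idx.sort()
        return GenotypeMatrix(
            self.samples,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosage[:, idx],
        )

    def subset_samples(self, sample_ids: Sequence) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants.copy(), self.dosage[idx])


class VariantStats(NamedTuple):
    maf: np.ndarray
    het_rate: np.ndarray
    missing_rate: np.ndarray


class PCAResult(NamedTuple):
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # variants x components


def variant_stats(G: GenotypeMatrix) -> VariantStats:
    """Per-variant MAF, heterozygous rate, and missing rate (non-missing calls)."""
    d = G.dosage
    miss = np.isnan(d)
    n_called = (~miss).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(d, axis=0) / (2.0 * n_called)
        het = np.nansum(d == 1.0, axis=0) / n_called
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    return VariantStats(maf, het, miss.mean(axis=0))


def variant_stats_and_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.1,
    het_max: float = 0.1,
    max_missing: float = 0.0,
    impute: bool = False,
    exempt_indels_from_maf: bool = False,
) -> GenotypeMatrix:
    """Drop variants failing MAF / heterozygosity / missingness thresholds.

    Boundary values are retained (MAF >= maf_min, het <= het_max, missing
    <= max_missing). With ``impute``, residual missing dosages are replaced
    by the variant mean rounded to the nearest of {0, 1, 2} (ties toward 1).
    ``exempt_indels_from_maf`` applies the MAF filter to SNPs only, for
    panels where InDels are gated on completeness alone.
    """
    st = variant_stats(G)
    with np.errstate(invalid="ignore"):
        maf_ok = st.maf >= maf_min
    if exempt_indels_from_maf:
        maf_ok = maf_ok | G.variants["is_indel"].to_numpy()
    keep = maf_ok & (st.het_rate <= het_max) & (st.missing_rate <= max_missing)
    keep &= ~np.isnan(st.maf)  # variants with zero called samples
    if not keep.any():
        warnings.warn("all variants removed by filters; returning empty matrix")
    out = G.subset_variants(keep)
    if impute and np.isnan(out.dosage).any():
        d = out.dosage.copy()
        means = np.nanmean(d, axis=0)
        # nearest of {0,1,2}; ties (x.5) resolve toward 1
        cand = np.array([0.0, 1.0, 2.0])
        dist = np.abs(means[:, None] - cand[None, :])
        dist[:, 1] -= 1e-12  # tie-break toward the middle class
        fill = cand[np.argmin(dist, axis=1)]
        ii, jj = np.where(np.isnan(d))
        d[ii, jj] = fill[jj]
        out = GenotypeMatrix(out.samples, out.variants, d)
    return out


def pairwise_r2(d1, d2) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(d1) | np.isnan(d2))
    a, b = d1[ok], d2[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant dosage vector; r2 defined as 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _window_r2(D: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of dosage columns (no missing data expected)."""
    X = D - D.mean(axis=0)
    sd = np.sqrt((X * X).sum(axis=0))
    sd[sd == 0] = np.nan
    C = (X.T @ X) / np.outer(sd, sd)
    return C * C


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.99,
) -> list:
    """Greedy windowed LD pruning; returns ids of retained variants.

    Mirrors the classic sliding-window pruner: within each window of
    ``window`` variants (slid by ``step``, left to right per chromosome),
    the first retained pair (in position order) with r^2 > ``r2_max`` loses
    its lower-MAF member (tie: the later variant by position); repeated
    until no retained pair in the window violates the threshold.
    """
    maf = variant_stats(G).maf
    keep = np.ones(G.n_variants, dtype=bool)
    chroms = G.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(cidx), step):
            widx = cidx[start : start + window]
            if len(widx) < 2:
                continue
            r2 = _window_r2(G.dosage[:, widx])
            changed = True
            while changed:
                changed = False
                alive = np.flatnonzero(keep[widx])
                for ai in range(len(alive)):
                    for bi in range(ai + 1, len(alive)):
                        i, j = alive[ai], alive[bi]
                        if r2[i, j] > r2_max:
                            gi, gj = widx[i], widx[j]
                            if maf[gi] < maf[gj]:
                                drop = gi
                            elif maf[gj] < maf[gi]:
                                drop = gj
                            else:
                                drop = gj  # tie: later position
                            keep[drop] = False
                            changed = True
                            break
                    if changed:
                        break
            if start + window >= len(cidx):
                break
    return G.variants.loc[keep, "id"].tolist()


def compute_pcs(G: GenotypeMatrix, n_components: int = 5) -> PCAResult:
    """Principal components of the dosage matrix (samples as observations).

    Columns are mean-centered, not scaled. Scores are ordered by decreasing
    explained variance; each component's sign is fixed so that its
    largest-magnitude variant loading is positive.
    """
    if n_components > min(G.n_samples, G.n_variants):
        raise ValueError("n_components exceeds matrix rank bound")
    if np.isnan(G.dosage).any():
        raise ValueError("missing dosages; impute before PCA")
    X = G.dosage - G.dosage.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    scores = (U * s)[:, :n_components]
    return PCAResult(scores, evr[:n_components], Vt[:n_components].T)


def select_diverse_subset(
    G: GenotypeMatrix,
    n_clusters: int,
    snps_per_chrom: int = 1000,
    seed: int = 0,
    maf_min: float = 0.05,
    het_max: float = 0.2,
) -> list:
    """Pick one representative (cluster medoid) per Ward cluster.

    Pre-filters variants (MAF > ``maf_min`` strict, het <= ``het_max``, no
    missing calls), subsamples up to ``snps_per_chrom`` variants per
    chromosome (seeded), computes Euclidean distances between samples, cuts
    a Ward dendrogram into ``n_clusters`` and returns each cluster's medoid
    (minimum mean within-cluster distance; ties by lexicographic sample id).
    """
    if n_clusters > G.n_samples:
        raise ValueError("n_clusters exceeds number of samples")
    st = variant_stats(G)
    ok = (st.maf > maf_min) & (st.het_rate <= het_max) & (st.missing_rate == 0)
    Gf = G.subset_variants(ok)
    rng = np.random.default_rng(seed)
    chroms = Gf.variants["chrom"].to_numpy()
    pick = []
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        if len(cidx) > snps_per_chrom:
            cidx = np.sort(rng.choice(cidx, size=snps_per_chrom, replace=False))
        else:
            warnings.warn(
                f"chromosome {chrom}: only {len(cidx)} eligible variants "
                f"(< {snps_per_chrom}); using all"
            )
        pick.extend(cidx.tolist())
    D = Gf.dosage[:, pick]
    dist = pdist(D, metric="euclidean")
    labels = fcluster(linkage(dist, method="ward"), n_clusters, criterion="maxclust")
    sq = squareform(dist)
    reps = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        mean_d = sq[np.ix_(members, members)].mean(axis=1)
        best = mean_d.min()
        tied = members[np.isclose(mean_d, best)]
        reps.append(min(G.samples[i] for i in tied))
    return sorted(reps)
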