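"""Response-eQTL detection: candidate selection, interaction mixed model,
reGene classification, and heat-expressed-only eGene calling.

A response eQTL (reQTL) is a cis variant whose effect on a gene's expression
differs between control and heat conditions. For each commonly expressed
eGene, the top cis variant per condition is selected (merging the two
conditions' picks by LD), and the genotype x condition interaction is tested
in a linear mixed model with a random intercept per genotype:

    E = intercept + d + c + X + X:c + d:c + (1 | genotype)

where d is allele dosage, c the condition indicator (control=0, heat=1) and
X the sample-level covariates. The d:c coefficient is tested with a
Satterthwaite-df t-test and Bonferroni-adjusted over the tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionPair
from .genotypes import GenotypeMatrix, pairwise_r2
from .lmm import RandomInterceptLMM

__all__ = [
    "InteractionFit",
    "select_candidates",
    "fit_interaction_lmm",
    "call_reqtls",
    "classify_regenes",
    "detect_heo_egenes",
    "rescan_flanking",
]

REGENE_CATEGORIES = ("RefControl", "RefHeat", "AltControl", "AltHeat")


@dataclass
class InteractionFit:
    """One gene/variant genotype-by-condition interaction test."""

    gene_id: str
    variant_id: str
    beta_interaction: float
    se: float
    df_satterthwaite: float
    p_raw: float
    n_genotypes: int
    converged: bool = True
    p_bonf: float = field(default=np.nan)
    is_reqtl: bool = field(default=False)


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


def select_candidates(
    hits_control: pd.DataFrame,
    hits_heat: pd.DataFrame,
    G: GenotypeMatrix,
    genes=None,
    r2_ld: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Pick at most two candidate cis variants per gene for interaction testing.

    Per condition the top cis hit (smallest p; ties broken by a seeded
    uniform draw) is taken. A gene significant in both conditions
    contributes one candidate if the two picks are identical
    (``identical_top``) or in high LD, r^2 > ``r2_ld`` (``high_ld_pick``,
    seeded random choice between them), and both picks when r^2 <= ``r2_ld``
    (``low_ld_both``). A gene significant in one condition contributes that
    condition's pick (``single_condition``). ``genes``, if given, restricts
    to genes expressed in both conditions.
    """
    rng = np.random.default_rng(seed)

    def top_per_gene(hits):
        out = {}
        cis = hits[hits["klass"] == "cis"]
        for gene, grp in cis.groupby("gene_id", sort=True):
            best = grp[grp["p"] == grp["p"].min()]
            row = best.iloc[rng.integers(0, len(best))] if len(best) > 1 else best.iloc[0]
            out[gene] = row["variant_id"]
        return out

    top_c = top_per_gene(hits_control)
    top_h = top_per_gene(hits_heat)
    gene_pool = set(top_c) | set(top_h)
    if genes is not None:
        gene_pool &= set(genes)
    rows = []
    for gene in sorted(gene_pool):
        vc, vh = top_c.get(gene), top_h.get(gene)
        if vc is not None and vh is not None:
            if vc == vh:
                rows.append((gene, vc, "identical_top"))
            else:
                r2 = pairwise_r2(G.dosage_of(vc), G.dosage_of(vh))
                if r2 > r2_ld:
                    pick = (vc, vh)[int(rng.integers(0, 2))]
                    rows.append((gene, pick, "high_ld_pick"))
                else:
                    rows.append((gene, vc, "low_ld_both"))
                    rows.append((gene, vh, "low_ld_both"))
        else:
            rows.append((gene, vc if vc is not None else vh, "single_condition"))
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "selection_rule"])


def fit_interaction_lmm(
    expr_control,
    expr_heat,
    dosage,
    covariates,
    genotype_ids=None,
    gene_id: str = "",
    variant_id: str = "",
) -> InteractionFit:
    """REML fit of the interaction mixed model for one gene/variant pair.

    ``expr_control``/``expr_heat`` are per-genotype transformed expression
    (length n); ``dosage`` the variant's alt dose per genotype; and
    ``covariates`` either an (n, k) matrix of condition-invariant covariates
    or a (2n, k) matrix with the n control rows first. Genotypes with a
    missing value in either condition are dropped (complete-pairs design).
    """
    yc = np.asarray(expr_control, dtype=float)
    yh = np.asarray(expr_heat, dtype=float)
    d = np.asarray(dosage, dtype=float)
    n = yc.size
    if genotype_ids is None:
        genotype_ids = np.arange(n)
    genotype_ids = np.asarray(genotype_ids)
    cov = np.asarray(covariates, dtype=float) if covariates is not None else np.zeros((n, 0))
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] == n:
        cov2 = np.vstack([cov, cov])
    elif cov.shape[0] == 2 * n:
        cov2 = cov
    else:
        raise ValueError("covariates must have n or 2n rows")

    ok = ~(np.isnan(yc) | np.isnan(yh) | np.isnan(d))
    ok &= ~np.isnan(cov2[:n]).any(axis=1) & ~np.isnan(cov2[n:]).any(axis=1)
    n_used = int(ok.sum())
    if n_used < 3:
        raise ValueError("fewer than 3 complete genotype pairs")
    if np.ptp(d[ok]) == 0:
        raise ValueError("dosage is constant on complete pairs")
    keep2 = np.concatenate([ok, ok])

    y = np.concatenate([yc, yh])[keep2]
    dd = np.concatenate([d, d])[keep2]
    cc = np.concatenate([np.zeros(n), np.ones(n)])[keep2]
    Xcov = cov2[keep2]
    groups = np.concatenate([genotype_ids, genotype_ids])[keep2]
    X = np.column_stack([np.ones(y.size), dd, cc, Xcov, Xcov * cc[:, None], dd * cc])
    model = RandomInterceptLMM(y, X, groups).fit()
    try:
        test = model.test(X.shape[1] - 1)
    except ValueError:
        return InteractionFit(
            gene_id, variant_id, np.nan, np.nan, np.nan, np.nan, n_used, converged=False
        )
    return InteractionFit(
        gene_id,
        variant_id,
        test.estimate,
        test.se,
        test.df,
        test.pvalue,
        n_used,
    )


def call_reqtls(fits, alpha: float = 0.01) -> pd.DataFrame:
    """Bonferroni-adjust interaction p-values and flag reQTLs.

    ``m`` is the number of tested gene/variant pairs. When both of a gene's
    two candidates pass, the smaller-p one is retained as the gene's reQTL
    (``is_gene_reqtl``); ``is_reqtl`` marks every passing test.
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    df = df.copy()
    m = len(df)
    df["p_bonf"] = np.minimum(1.0, df["p_raw"] * m)
    df["is_reqtl"] = df["p_bonf"] < alpha
    df["is_gene_reqtl"] = False
    passing = df[df["is_reqtl"]]
    for gene, grp in passing.groupby("gene_id"):
        best = grp["p_raw"].idxmin()
        df.loc[best, "is_gene_reqtl"] = True
    return df


def _allele_group_medians(pair: ExpressionPair, gene_id: str, d: np.ndarray):
    gi = pair.gene_index([gene_id])[0]
    ref = d == 0
    alt = d == 2
    med = {}
    for name, mask in (("ref", ref), ("alt", alt)):
        med[name] = (
            float(np.median(pair.cpm_control[gi, mask])),
            float(np.median(pair.cpm_heat[gi, mask])),
        )
    return med, int(ref.sum()), int(alt.sum())


def classify_regenes(
    calls: pd.DataFrame,
    pair: ExpressionPair,
    G: GenotypeMatrix,
    min_group: int = 3,
) -> pd.DataFrame:
    """Assign each reQTL gene one of the four response categories.

    Heterozygotes are excluded; per homozygous allele group the response is
    ``L = log2((median CPM_heat + 1) / (median CPM_control + 1))``. The
    prefix is Ref when |L_ref| > |L_alt| (Alt when smaller; exact ties are
    ambiguous and excluded), and the suffix is Heat when the larger-|L|
    allele responds upward (L > 0), Control otherwise. Genes with fewer than
    ``min_group`` genotypes in either homozygous class are skipped.
    """
    rows = []
    for row in calls.itertuples():
        d = G.dosage_of(row.variant_id)
        med, n_ref, n_alt = _allele_group_medians(pair, row.gene_id, d)
        if n_ref < min_group or n_alt < min_group:
            rows.append((row.gene_id, row.variant_id, "skipped_small_group",
                         np.nan, np.nan, n_ref, n_alt))
            continue
        L_ref = np.log2((med["ref"][1] + 1.0) / (med["ref"][0] + 1.0))
        L_alt = np.log2((med["alt"][1] + 1.0) / (med["alt"][0] + 1.0))
        if np.abs(L_ref) == np.abs(L_alt):
            cat = "ambiguous"
        else:
            prefix = "Ref" if abs(L_ref) > abs(L_alt) else "Alt"
            big = L_ref if prefix == "Ref" else L_alt
            cat = prefix + ("Heat" if big > 0 else "Control")
        rows.append((row.gene_id, row.variant_id, cat, L_ref, L_alt, n_ref, n_alt))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "variant_id", "category", "L_ref", "L_alt",
                 "n_ref_hom", "n_alt_hom"],
    )


def detect_heo_egenes(
    heat_only_genes,
    hits_heat: pd.DataFrame,
    pair: ExpressionPair,
    G: GenotypeMatrix,
    min_group: int = 3,
) -> pd.DataFrame:
    """Heat-expressed-only eGenes with an allele-level activation class.

    A heo-eGene is a gene expressed only under heat that has at least one
    significant cis hit in the heat-condition scan. Its class compares the
    median heat CPM between ref- and alt-homozygous genotypes at the top cis
    variant: the allele with greater median heat expression names the class
    (RefHeat / AltHeat); exact ties are ambiguous and excluded.
    """
    cis = hits_heat[hits_heat["klass"] == "cis"]
    rows = []
    for gene in sorted(set(heat_only_genes)):
        ghits = cis[cis["gene_id"] == gene]
        if ghits.empty:
            continue
        best = ghits.sort_values(
            ["p", "distance_bp", "variant_id"],
            key=lambda s: s.abs() if s.name == "distance_bp" else s,
        ).iloc[0]
        d = G.dosage_of(best["variant_id"])
        med, n_ref, n_alt = _allele_group_medians(pair, gene, d)
        if n_ref < min_group or n_alt < min_group:
            rows.append((gene, best["variant_id"], "skipped_small_group",
                         np.nan, np.nan, n_ref, n_alt))
            continue
        mr, ma = med["ref"][1], med["alt"][1]
        if mr == ma:
            cat = "ambiguous"
        else:
            cat = "RefHeat" if mr > ma else "AltHeat"
        rows.append((gene, best["variant_id"], cat, mr, ma, n_ref, n_alt))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "variant_id", "category", "median_heat_cpm_ref",
                 "median_heat_cpm_alt", "n_ref_hom", "n_alt_hom"],
    )


def rescan_flanking(
    gene: pd.Series,
    G: GenotypeMatrix,
    expr_control,
    expr_heat,
    covariates,
    flank_bp: int = 1000,
) -> pd.DataFrame:
    """Interaction fits for every variant in the gene body +- ``flank_bp``.

    Boundaries are inclusive. Raw (unadjusted) interaction p-values are
    returned — these feed the inside/outside footprint comparison, not a
    second round of genome-wide calling. Variants that are constant over the
    panel are skipped.
    """
    lo, hi = gene.start - flank_bp, gene.end + flank_bp
    v = G.variants
    sel = np.flatnonzero(
        (v["chrom"].to_numpy() == gene.chrom)
        & (v["pos"].to_numpy() >= lo)
        & (v["pos"].to_numpy() <= hi)
    )
    rows = []
    for j in sel:
        d = G.dosage[:, j]
        if np.ptp(d[~np.isnan(d)]) == 0:
            continue
        fit = fit_interaction_lmm(
            expr_control, expr_heat, d, covariates,
            gene_id=gene.gene_id, variant_id=v.iloc[j]["id"],
        )
        rows.append((fit.variant_id, int(v.iloc[j]["pos"]), fit.beta_interaction,
                     fit.se, fit.df_satterthwaite, fit.p_raw))
    if not rows:
        warnings.warn(f"no variants within {flank_bp} bp of gene {gene.gene_id}")
    return pd.DataFrame(
        rows, columns=["variant_id", "pos", "beta_interaction", "se",
                       "df_satterthwaite", "p_raw"]
    )
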