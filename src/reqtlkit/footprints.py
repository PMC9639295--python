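"""TF-footprint interval handling and variant prioritization.

Footprints are BED-style intervals (0-based, half-open) carrying a
differential-occupancy status between control and heat conditions
(``stable`` / ``heat_enriched`` / ``heat_depleted``). This module centers raw
chromatin fragments to 20-bp footprint-resolution windows, calls
differential occupancy from replicate counts, assigns footprints to genes
(2-kb flanks, promoters, gene bodies), tests enrichment of heat-enriched
footprints near upregulated genes, and compares interaction effects for
variants inside vs. outside heat-enriched footprints.

Gene coordinates are 1-based inclusive; a variant at 1-based position p
occupies the 0-based base [p-1, p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, fisher_exact, rank_sum

__all__ = [
    "center_fragments",
    "differential_occupancy",
    "assign_footprints",
    "enrichment_vs_background",
    "top_variant_overlap",
    "inside_outside_comparison",
    "relative_position",
]

STATUSES = ("stable", "heat_enriched", "heat_depleted")
REPLICATE_COLUMNS = ["control_1", "control_2", "control_3", "heat_1", "heat_2", "heat_3"]


def center_fragments(
    fragments: pd.DataFrame,
    out_width: int = 20,
    max_len: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Shorten fragments to fixed-width windows centered on their midpoint.

    Fragments longer than ``max_len`` (or shorter than ``out_width``) are
    dropped — only the short-fragment fraction marks TF footprints.
    Odd-length fragments have a unique middle base; even-length fragments
    pick one of the two middle bases with a seeded coin flip. Windows are
    clamped into the fragment, so outputs are exactly ``out_width`` bp,
    0-based half-open, and always within the original bounds (the clamp only
    binds for fragments of exactly ``out_width`` bp).
    """
    rng = np.random.default_rng(seed)
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    length = end - start
    keep = (length <= max_len) & (length >= out_width)
    start, end, length = start[keep], end[keep], length[keep]
    mid = start + length // 2
    even = length % 2 == 0
    # even length: two central candidates start+len/2-1 and start+len/2
    mid = mid - (even & (rng.uniform(size=mid.size) < 0.5)).astype(int)
    lo = np.clip(mid - out_width // 2, start, end - out_width)
    out = fragments.loc[keep].copy()
    out["start"] = lo
    out["end"] = lo + out_width
    return out.reset_index(drop=True)


def differential_occupancy(
    fp: pd.DataFrame, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Call per-footprint differential occupancy from replicate counts.

    Replicate counts are normalized to counts-per-million of the per-replicate
    interval totals, log2(x+1) transformed and compared with a Welch two-sample
    t-test (heat vs control); BH adjustment across intervals. Status is
    ``heat_enriched``/``heat_depleted`` when adjusted p < ``fdr_max`` with the
    heat mean above/below the control mean, else ``stable``.
    """
    missing = [c for c in REPLICATE_COLUMNS if c not in fp.columns]
    if missing:
        raise ValueError(
            f"replicate count columns {missing} absent; supply pre-called "
            "statuses instead"
        )
    counts = fp[REPLICATE_COLUMNS].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("a replicate has zero total counts")
    logcpm = np.log2(counts / totals * 1e6 + 1.0)
    ctrl, heat = logcpm[:, :3], logcpm[:, 3:]
    mc, mh = ctrl.mean(axis=1), heat.mean(axis=1)
    vc, vh = ctrl.var(axis=1, ddof=1), heat.var(axis=1, ddof=1)
    nc = nh = 3
    se2 = vc / nc + vh / nh
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (mh - mc) / np.sqrt(se2)
        df = se2**2 / ((vc / nc) ** 2 / (nc - 1) + (vh / nh) ** 2 / (nh - 1))
    from scipy import stats as sps

    p = np.where(
        se2 > 0, 2.0 * sps.t.sf(np.abs(tstat), np.where(se2 > 0, df, 1.0)), 1.0
    )
    p = np.where(np.isnan(p), 1.0, p)
    fdr = adjust_pvalues(p, method="bh")
    status = np.where(
        (fdr < fdr_max) & (mh > mc),
        "heat_enriched",
        np.where((fdr < fdr_max) & (mh < mc), "heat_depleted", "stable"),
    )
    out = fp.copy()
    out["status"] = status
    out["fdr"] = fdr
    return out


def _overlapping(fp_chrom, fp_start, fp_end, chrom, lo0, hi0) -> np.ndarray:
    """Indices of footprints sharing >= 1 base with [lo0, hi0) on chrom."""
    return np.flatnonzero((fp_chrom == chrom) & (fp_start < hi0) & (fp_end > lo0))


def assign_footprints(
    fp: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 2000
) -> pd.DataFrame:
    """Assign footprints to genes: 2-kb flank, promoter, and gene body sets.

    The flank is the gene body extended by ``flank_bp`` on both sides; the
    promoter is the ``flank_bp`` window immediately upstream of the TSS on
    the strand-appropriate side. Overlap means at least one shared base; a
    footprint may be assigned to several genes. Footprint index arrays refer
    to ``fp``'s positional rows.
    """
    fc = fp["chrom"].to_numpy()
    fs = fp["start"].to_numpy()
    fe = fp["end"].to_numpy()
    status = fp["status"].to_numpy()
    rows = []
    for g in genes.itertuples():
        body0 = (g.start - 1, g.end)  # 0-based half-open
        flank0 = (body0[0] - flank_bp, body0[1] + flank_bp)
        if g.strand == "+":
            prom0 = (body0[0] - flank_bp, body0[0])
        else:
            prom0 = (body0[1], body0[1] + flank_bp)
        in_flank = _overlapping(fc, fs, fe, g.chrom, *flank0)
        in_prom = _overlapping(fc, fs, fe, g.chrom, *prom0)
        in_body = _overlapping(fc, fs, fe, g.chrom, *body0)
        rows.append(
            (
                g.gene_id,
                in_flank,
                in_prom,
                in_body,
                bool((status[in_flank] == "heat_enriched").any()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "footprints_flank", "footprints_promoter",
                 "footprints_gene_body", "has_heat_enriched"],
    )


def enrichment_vs_background(
    assignments: pd.DataFrame, upregulated, background
) -> tuple[np.ndarray, float]:
    """2x2 Fisher enrichment of heat-enriched footprints near upregulated genes.

    Rows: upregulated / background gene set; columns: has / lacks a
    heat-enriched footprint within the 2-kb flank. One-sided (greater) p.
    """
    up = set(upregulated)
    bg = set(background)
    if up & bg:
        raise ValueError("gene sets must be disjoint")
    has = dict(zip(assignments["gene_id"], assignments["has_heat_enriched"]))
    a = sum(1 for g in up if has.get(g, False))
    b = len(up) - a
    c = sum(1 for g in bg if has.get(g, False))
    d = len(bg) - c
    table = np.array([[a, b], [c, d]])
    return table, fisher_exact(table, alternative="greater")


def _variant_inside(fp: pd.DataFrame, status_filter: str, chrom, pos_1based) -> bool:
    pos0 = int(pos_1based) - 1
    sel = fp["status"].to_numpy() == status_filter
    return bool(
        (
            (fp["chrom"].to_numpy() == chrom)
            & sel
            & (fp["start"].to_numpy() <= pos0)
            & (fp["end"].to_numpy() > pos0)
        ).any()
    )


def top_variant_overlap(
    per_gene_results: dict,
    fp: pd.DataFrame,
    gene_info: pd.DataFrame,
    categories: dict | None = None,
    top_k: int = 3,
    status_filter: str = "heat_enriched",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag genes whose top-associated variants sit in (heat-enriched) footprints.

    ``per_gene_results`` maps gene_id -> DataFrame with variant_id, pos and
    p_raw columns (e.g. from :func:`reqtlkit.reqtl.rescan_flanking`).
    Variants are ranked by raw p ascending, ties by distance to the gene's
    TSS then position; the gene is flagged if any of the ``top_k`` variants
    falls inside a ``status_filter`` interval. Returns the per-gene flags and
    per-category flagged proportions (category "all" when none supplied).
    """
    tss = dict(zip(gene_info["gene_id"], gene_info["tss"]))
    chrom = dict(zip(gene_info["gene_id"], gene_info["chrom"]))
    rows = []
    for gene, res in per_gene_results.items():
        if res.empty:
            continue
        r = res.copy()
        r["_dist_tss"] = (r["pos"] - tss[gene]).abs()
        r = r.sort_values(["p_raw", "_dist_tss", "pos"], kind="stable").head(top_k)
        flag = any(
            _variant_inside(fp, status_filter, chrom[gene], p) for p in r["pos"]
        )
        cat = categories.get(gene, "all") if categories else "all"
        rows.append((gene, cat, flag))
    flags = pd.DataFrame(rows, columns=["gene_id", "category", "flagged"])
    props = (
        flags.groupby("category")["flagged"]
        .agg(n="size", proportion="mean")
        .reset_index()
    )
    return flags, props


def inside_outside_comparison(
    per_gene_results: dict,
    fp: pd.DataFrame,
    gene_info: pd.DataFrame,
    categories: dict | None = None,
    status_filter: str = "heat_enriched",
) -> pd.DataFrame:
    """Rank-sum comparison of interaction signal inside vs outside footprints.

    Pools ``-log10(raw interaction p)`` across each category's genes and
    splits variants by whether they lie inside any ``status_filter``
    interval; two-sided Mann-Whitney test per category. Categories with an
    empty side are reported with NaN statistics.
    """
    chrom = dict(zip(gene_info["gene_id"], gene_info["chrom"]))
    pooled: dict = {}
    for gene, res in per_gene_results.items():
        cat = categories.get(gene, "all") if categories else "all"
        d = pooled.setdefault(cat, {"in": [], "out": []})
        for row in res.itertuples():
            if not np.isfinite(row.p_raw):
                continue
            val = -np.log10(max(row.p_raw, 1e-300))
            side = "in" if _variant_inside(fp, status_filter, chrom[gene], row.pos) else "out"
            d[side].append(val)
    rows = []
    for cat, d in sorted(pooled.items()):
        n_in, n_out = len(d["in"]), len(d["out"])
        if n_in == 0 or n_out == 0:
            rows.append((cat, n_in, n_out, np.nan, np.nan, np.nan, np.nan))
            continue
        stat, p = rank_sum(d["in"], d["out"])
        rows.append(
            (cat, n_in, n_out, stat, p,
             float(np.median(d["in"])), float(np.median(d["out"])))
        )
    return pd.DataFrame(
        rows,
        columns=["category", "n_in", "n_out", "statistic", "p",
                 "median_in", "median_out"],
    )


def relative_position(
    midpoint: int, gene: pd.Series, proximal_bp: int = 2000, chrom=None
) -> tuple[int, int, str]:
    """Strand-aware signed distances of a feature midpoint to TSS and TTS.

    Upstream of the gene is negative. The positional class is ``genic``
    inside [start, end] (TSS itself included), ``proximal_up/downstream``
    within ``proximal_bp`` of the gene edges, else distal. Passing the
    feature's ``chrom`` asserts it matches the gene's chromosome.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError("feature and gene are on different chromosomes")
    sign = 1 if gene.strand == "+" else -1
    d_tss = sign * (midpoint - gene.tss)
    d_tts = sign * (midpoint - gene.tts)
    if gene.start <= midpoint <= gene.end:
        klass = "genic"
    elif d_tss < 0:
        klass = "proximal_upstream" if -d_tss <= proximal_bp else "distal_upstream"
    else:
        klass = "proximal_downstream" if d_tts <= proximal_bp else "distal_downstream"
    return int(d_tss), int(d_tts), klass
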