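"""Config-driven orchestration of the full response-eQTL analysis.

Stage order mirrors the analysis: genotype QC -> LD pruning -> structure PCs
-> expression normalization and expressed sets -> hidden factors ->
per-condition eQTL scans -> trans hotspots -> reQTL candidates, interaction
tests and classification -> heo-eGene detection -> footprint integration.
Inputs come either from files or from the synthetic-cohort generator; every
random stage derives its stream from the single global seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .eqtl import detect_hotspots, scan_associations
from .expression import (
    ExpressionPair,
    consistent_upregulation,
    expressed_gene_sets,
    infer_hidden_factors,
    inverse_normal_transform,
    paired_de,
    screen_genetic_factors,
)
from .footprints import (
    assign_footprints,
    differential_occupancy,
    enrichment_vs_background,
    inside_outside_comparison,
    top_variant_overlap,
)
from .genotypes import compute_pcs, ld_prune, variant_stats_and_filter
from .reqtl import (
    call_reqtls,
    classify_regenes,
    detect_heo_egenes,
    fit_interaction_lmm,
    fits_to_frame,
    rescan_flanking,
    select_candidates,
)
from .simulate import (
    REQTL_CLASSES,
    HEO_CLASSES,
    SimConfig,
    generate_expression,
    generate_footprints,
    generate_gene_models,
    generate_genotypes,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_against_truth"]

log = logging.getLogger("reqtlkit")


@dataclass
class PipelineConfig:
    """All stage parameters plus either a simulate block or input paths."""

    simulate: SimConfig | None = None
    genotype_path: str | None = None
    counts_control_path: str | None = None
    counts_heat_path: str | None = None
    genes_path: str | None = None
    footprints_path: str | None = None
    out_dir: str | None = None
    seed: int = 0

    maf_min: float = 0.1
    het_max: float = 0.1
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.99
    n_pcs: int = 5
    n_factors: int = 5
    factor_genetic_r2_max: float = 0.25
    cpm_min: float = 1.0
    frac_min: float = 0.10
    de_p_adj_max: float = 0.01
    eqtl_p_adj_max: float = 0.01
    cis_window_bp: int = 1_000_000
    candidate_r2_ld: float = 0.8
    reqtl_alpha: float = 0.01
    rescan_flank_bp: int = 1000
    footprint_flank_bp: int = 2000
    footprint_fdr_max: float = 0.05
    run_footprints: bool = True
    run_rescan: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "libsize_range" in sim:
                sim["libsize_range"] = tuple(sim["libsize_range"])
            sim = SimConfig(**sim)
        cfg = cls(simulate=sim, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    def validate(self) -> None:
        if self.simulate is None and self.genotype_path is None:
            raise ValueError("either a simulate block or input paths are required")
        if self.simulate is None and self.run_footprints and self.footprints_path is None:
            raise ValueError(
                "footprint stage enabled but no footprints_path given"
            )
        for name in ("maf_min", "het_max", "frac_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0, 1]")
        for name in ("de_p_adj_max", "eqtl_p_adj_max", "reqtl_alpha",
                     "footprint_fdr_max", "candidate_r2_ld"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} out of (0, 1]")


@dataclass
class PipelineResult:
    config: PipelineConfig
    genotypes: object
    genes: pd.DataFrame
    pair: ExpressionPair
    pcs: np.ndarray
    sets: object
    de: pd.DataFrame
    consistent_up: set
    scans: dict
    hotspots: dict
    candidates: pd.DataFrame
    fits: pd.DataFrame
    regenes: pd.DataFrame
    heo: pd.DataFrame
    footprints: pd.DataFrame | None
    footprint_results: dict
    truth: pd.DataFrame | None
    summary: dict
    rescans: dict = field(default_factory=dict)


def _transform_rows(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(inverse_normal_transform, 1, M)


def _stage(summary, name, t0):
    summary["stage_seconds"][name] = round(time.perf_counter() - t0, 3)
    log.info("stage %s done (%.2fs)", name, summary["stage_seconds"][name])
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    summary: dict = {"seed": config.seed, "stage_seconds": {}, "counts": {}}
    t0 = time.perf_counter()

    # ---- inputs ------------------------------------------------------------
    truth = None
    footprints = None
    if config.simulate is not None:
        sim = config.simulate
        G = generate_genotypes(sim)
        genes = generate_gene_models(sim)
        pair, truth = generate_expression(G, genes, sim)
        if config.run_footprints:
            footprints = generate_footprints(truth, genes, G, sim)
    else:
        gp = str(config.genotype_path)
        G = rio.read_vcf(gp) if gp.endswith(".vcf") else rio.read_dosage_tsv(gp)
        genes = rio.read_genes_tsv(config.genes_path)
        pair = rio.read_expression_pair(
            config.counts_control_path, config.counts_heat_path
        )
        if config.run_footprints:
            footprints = rio.read_footprints_bed(config.footprints_path)
    t0 = _stage(summary, "inputs", t0)

    # ---- genotype QC, pruning, structure PCs -------------------------------
    Gf = variant_stats_and_filter(
        G, maf_min=config.maf_min, het_max=config.het_max, impute=True
    )
    kept = ld_prune(
        Gf, window=config.ld_window, step=config.ld_step, r2_max=config.ld_r2_max
    )
    Gp = Gf.subset_variants(kept)
    pca = compute_pcs(Gp, n_components=config.n_pcs)
    pcs = pca.scores
    summary["counts"]["variants_raw"] = G.n_variants
    summary["counts"]["variants_filtered"] = Gf.n_variants
    summary["counts"]["variants_pruned"] = Gp.n_variants
    summary["pc_explained_variance"] = [float(x) for x in pca.explained_variance_ratio]
    t0 = _stage(summary, "genotype_qc", t0)

    # ---- expression sets, DE, consistency ----------------------------------
    sets = expressed_gene_sets(pair, cpm_min=config.cpm_min, frac_min=config.frac_min)
    tested_genes = sorted(sets.control | sets.heat)
    de = paired_de(pair, genes=tested_genes, p_adj_max=config.de_p_adj_max)
    cup = consistent_upregulation(pair, genes=tested_genes)
    summary["counts"].update(
        expressed_control=len(sets.control),
        expressed_heat=len(sets.heat),
        expressed_common=len(sets.common),
        control_only=len(sets.control_only),
        heat_only=len(sets.heat_only),
        up_DEG=int(de["up_DEG"].sum()),
        down_DEG=int(de["down_DEG"].sum()),
        consistent_up=len(cup),
    )
    t0 = _stage(summary, "expression", t0)

    # ---- per-condition scans ------------------------------------------------
    gene_pos = {g: i for i, g in enumerate(pair.genes)}
    scans, hotspots = {}, {}
    factors_by_cond = {}
    for cond, cpm, gene_set in (
        ("control", pair.cpm_control, sets.control),
        ("heat", pair.cpm_heat, sets.heat),
    ):
        idx = np.array([gene_pos[g] for g in sorted(gene_set)])
        sub_genes = genes.set_index("gene_id").loc[
            [pair.genes[i] for i in idx]
        ].reset_index()
        E = _transform_rows(cpm[idx])
        factors = infer_hidden_factors(E, k=config.n_factors, known_covariates=pcs)
        factors = screen_genetic_factors(
            factors, Gf.dosage, r2_max=config.factor_genetic_r2_max
        )
        factors_by_cond[cond] = factors
        cov = np.column_stack([pcs, factors]) if config.n_factors else pcs
        res = scan_associations(
            E, Gf, cov, sub_genes,
            p_adj_max=config.eqtl_p_adj_max,
            cis_window_bp=config.cis_window_bp,
            condition=cond,
        )
        scans[cond] = res
        trans_hits = res.hits[res.hits["klass"] == "trans"]
        hotspots[cond] = detect_hotspots(trans_hits, Gf.variants)
        summary["counts"][f"egenes_{cond}"] = int(
            res.hits.loc[res.hits["klass"] == "cis", "gene_id"].nunique()
        )
        summary["counts"][f"hotspots_{cond}"] = int(hotspots[cond]["is_hotspot"].sum())
    t0 = _stage(summary, "eqtl_scan", t0)

    # ---- reQTL candidates and interaction tests ----------------------------
    candidates = select_candidates(
        scans["control"].hits,
        scans["heat"].hits,
        Gf,
        genes=sets.common,
        r2_ld=config.candidate_r2_ld,
        seed=config.seed,
    )
    common_sorted = sorted(sets.common)
    idx_common = np.array([gene_pos[g] for g in common_sorted])
    # interaction model runs on log2(CPM+1): a per-condition rank transform
    # standardizes each condition's variance and thereby shrinks genuine
    # genotype-by-condition signal, so it is used for the scans only
    Ec = np.log2(pair.cpm_control[idx_common] + 1.0)
    Eh = np.log2(pair.cpm_heat[idx_common] + 1.0)
    # LMM covariates: structure PCs (condition-invariant) + hidden factors
    # inferred once from the column-stacked two-condition expression matrix,
    # assigned per sample-condition row.
    stacked = np.hstack([Ec, Eh])
    fac2 = infer_hidden_factors(
        stacked, k=config.n_factors, known_covariates=np.vstack([pcs, pcs])
    )
    fac2 = screen_genetic_factors(
        fac2, np.vstack([Gf.dosage, Gf.dosage]),
        r2_max=config.factor_genetic_r2_max,
    )
    n = len(pair.samples)
    cov2 = np.column_stack([np.vstack([pcs, pcs]), fac2])
    row_of = {g: i for i, g in enumerate(common_sorted)}
    fits = []
    for cand in candidates.itertuples():
        if cand.gene_id not in row_of:
            continue
        gi = row_of[cand.gene_id]
        fits.append(
            fit_interaction_lmm(
                Ec[gi], Eh[gi], Gf.dosage_of(cand.variant_id), cov2,
                genotype_ids=np.arange(n),
                gene_id=cand.gene_id, variant_id=cand.variant_id,
            )
        )
    fits_df = (
        call_reqtls(fits_to_frame(fits), alpha=config.reqtl_alpha)
        if fits
        else pd.DataFrame()
    )
    gene_calls = (
        fits_df[fits_df["is_gene_reqtl"]] if len(fits_df) else pd.DataFrame()
    )
    regenes = (
        classify_regenes(gene_calls, pair, Gf)
        if len(gene_calls)
        else pd.DataFrame(columns=["gene_id", "variant_id", "category",
                                   "L_ref", "L_alt", "n_ref_hom", "n_alt_hom"])
    )
    heo = detect_heo_egenes(sets.heat_only, scans["heat"].hits, pair, Gf)
    summary["counts"].update(
        tested_pairs=len(fits_df),
        reqtls=int(fits_df["is_reqtl"].sum()) if len(fits_df) else 0,
        regenes=int(
            regenes["category"].isin(
                ["RefControl", "RefHeat", "AltControl", "AltHeat"]
            ).sum()
        ),
        heo_egenes=int(
            heo["category"].isin(["RefHeat", "AltHeat"]).sum()
        ) if len(heo) else 0,
    )
    t0 = _stage(summary, "reqtl", t0)

    # ---- footprint integration ----------------------------------------------
    fp_results: dict = {}
    rescans: dict = {}
    if config.run_footprints and footprints is not None:
        if "status" not in footprints.columns:
            footprints = differential_occupancy(
                footprints, fdr_max=config.footprint_fdr_max
            )
        assignments = assign_footprints(
            footprints, genes, flank_bp=config.footprint_flank_bp
        )
        upregulated = set(cup)
        background = (sets.common - upregulated)
        table, enr_p = enrichment_vs_background(assignments, upregulated, background)
        fp_results["enrichment_table"] = table
        fp_results["enrichment_p"] = enr_p
        summary["footprint_enrichment_p"] = enr_p

        if config.run_rescan and len(regenes):
            cats = dict(zip(regenes["gene_id"], regenes["category"]))
            gene_rows = genes.set_index("gene_id")
            for gene_id in regenes["gene_id"]:
                if cats[gene_id] not in ("RefControl", "RefHeat", "AltControl", "AltHeat"):
                    continue
                grow = gene_rows.loc[gene_id]
                grow = pd.Series({**grow.to_dict(), "gene_id": gene_id})
                if gene_id not in row_of:
                    continue
                gi = row_of[gene_id]
                rescans[gene_id] = rescan_flanking(
                    grow, Gf, Ec[gi], Eh[gi], cov2, flank_bp=config.rescan_flank_bp
                )
            if rescans:
                flags, props = top_variant_overlap(
                    rescans, footprints, genes, categories=cats
                )
                fp_results["top_variant_flags"] = flags
                fp_results["top_variant_props"] = props
                fp_results["inside_outside"] = inside_outside_comparison(
                    rescans, footprints, genes, categories=cats
                )
        t0 = _stage(summary, "footprints", t0)

    result = PipelineResult(
        config=config,
        genotypes=Gf,
        genes=genes,
        pair=pair,
        pcs=pcs,
        sets=sets,
        de=de,
        consistent_up=cup,
        scans=scans,
        hotspots=hotspots,
        candidates=candidates,
        fits=fits_df,
        regenes=regenes,
        heo=heo,
        footprints=footprints,
        footprint_results=fp_results,
        truth=truth,
        summary=summary,
        rescans=rescans,
    )
    if truth is not None:
        summary["evaluation"] = evaluate_against_truth(result, truth).to_dict(
            orient="records"
        )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def evaluate_against_truth(result: PipelineResult, truth: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity / false-discovery / category-accuracy against planted truth."""
    truth = truth.set_index("gene_id")
    known = set(truth.index)
    res_genes = set(result.pair.genes)
    if not res_genes <= known:
        raise ValueError("truth table does not cover the analyzed genes")

    rows = []
    fits = result.fits
    called = (
        set(fits.loc[fits["is_gene_reqtl"], "gene_id"]) if len(fits) else set()
    )
    planted_reqtl = set(truth.index[truth["class"].isin(REQTL_CLASSES)])
    tested = set(fits["gene_id"]) if len(fits) else set()
    sens = (
        len(called & planted_reqtl) / len(planted_reqtl) if planted_reqtl else np.nan
    )
    fdp = (
        len(called - planted_reqtl) / len(called) if called else np.nan
    )
    rows.append(("reqtl", "sensitivity", sens))
    rows.append(("reqtl", "false_discovery_proportion", fdp))
    rows.append(("reqtl", "n_called", float(len(called))))

    if len(result.regenes):
        cls = result.regenes[
            result.regenes["category"].isin(
                ["RefControl", "RefHeat", "AltControl", "AltHeat"]
            )
        ]
        merged = cls.join(truth["class"], on="gene_id")
        is_planted = merged["class"].isin(REQTL_CLASSES)
        ok = (
            merged.loc[is_planted, "class"].str.replace("reqtl_", "", regex=False)
            == merged.loc[is_planted, "category"]
        )
        acc = float(ok.mean()) if is_planted.any() else np.nan
        rows.append(("regene", "category_accuracy", acc))

    planted_heo = set(truth.index[truth["class"].isin(HEO_CLASSES)])
    det_heo = (
        set(
            result.heo.loc[
                result.heo["category"].isin(["RefHeat", "AltHeat"]), "gene_id"
            ]
        )
        if len(result.heo)
        else set()
    )
    rows.append(
        (
            "heo",
            "recovery",
            len(det_heo & planted_heo) / len(planted_heo) if planted_heo else np.nan,
        )
    )
    if det_heo & planted_heo:
        sub = result.heo.set_index("gene_id").loc[sorted(det_heo & planted_heo)]
        ok = (
            "heo_" + sub["category"]
        ) == truth.loc[sub.index, "class"]
        rows.append(("heo", "category_accuracy", float(ok.mean())))

    # hotspot recovery: is the planted regulator's bin flagged?
    planted_reg = truth.loc[truth["hotspot_id"] != "", "causal_variant_id"].unique()
    if len(planted_reg):
        vinfo = result.genotypes.variants.set_index("id")
        found = 0
        hs = pd.concat(result.hotspots.values()) if result.hotspots else pd.DataFrame()
        hot = hs[hs["is_hotspot"]] if len(hs) else pd.DataFrame()
        for vid in planted_reg:
            if vid not in vinfo.index:
                continue
            b = ((vinfo.loc[vid, "pos"] - 1) // 10_000) * 10_000
            if len(hot) and (
                (hot["chrom"] == vinfo.loc[vid, "chrom"]) & (hot["bin_start"] == b)
            ).any():
                found += 1
        rows.append(("hotspot", "recovery", found / len(planted_reg)))

    if "top_variant_flags" in result.footprint_results:
        flags = result.footprint_results["top_variant_flags"]
        up_cats = {"RefHeat", "AltHeat"}
        sel = flags[flags["category"].isin(up_cats)]
        if len(sel):
            rows.append(
                ("footprint", "top_variant_recovery", float(sel["flagged"].mean()))
            )
    return pd.DataFrame(rows, columns=["component", "metric", "value"])


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    rio.write_dosage_tsv(result.genotypes, out / "genotypes_filtered.tsv")
    rio.write_genes_tsv(result.genes, out / "genes.tsv")
    rio.write_counts_tsv(
        result.pair.counts_control, result.pair.genes, result.pair.samples,
        out / "counts_control.tsv",
    )
    rio.write_counts_tsv(
        result.pair.counts_heat, result.pair.genes, result.pair.samples,
        out / "counts_heat.tsv",
    )
    pd.DataFrame(
        result.pcs,
        index=pd.Index(result.genotypes.samples, name="sample"),
        columns=[f"PC{i+1}" for i in range(result.pcs.shape[1])],
    ).to_csv(out / "pcs.tsv", sep="\t")
    result.de.to_csv(out / "paired_de.tsv", sep="\t", index=False)
    for cond, scan in result.scans.items():
        scan.hits.to_csv(out / f"eqtl_hits_{cond}.tsv", sep="\t", index=False)
        result.hotspots[cond].to_csv(
            out / f"hotspots_{cond}.tsv", sep="\t", index=False
        )
    result.candidates.to_csv(out / "reqtl_candidates.tsv", sep="\t", index=False)
    if len(result.fits):
        result.fits.to_csv(out / "interaction_fits.tsv", sep="\t", index=False)
    result.regenes.to_csv(out / "regenes.tsv", sep="\t", index=False)
    result.heo.to_csv(out / "heo_egenes.tsv", sep="\t", index=False)
    if result.footprints is not None:
        rio.write_footprints_bed(result.footprints, out / "footprints.bed")
    if result.truth is not None:
        result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=float)
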