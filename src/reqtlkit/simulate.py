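"""Synthetic paired-condition eQTL cohort with a machine-readable truth table.

Emulates the statistical structure of a diversity panel of inbred lines
profiled by RNA-seq under control and heat conditions:

* near-homozygous genotypes ({0, 2} dosages with a small heterozygosity
  leak) in LD blocks, with mild population structure from the
  Balding-Nichols model;
* negative-binomial counts whose log2 mean is additive in a cis allele
  dosage, a condition main effect, a genotype-by-condition interaction,
  sparse hidden-factor loadings and a per-genotype random intercept;
* planted gene classes — cis-only eGenes, the four response-eQTL (reQTL)
  categories, heat-expressed-only (heo) genes with allele-dependent
  activation, consistently upregulated genes, and trans-regulator hotspot
  targets;
* TF-footprint intervals around TSSs, with heat-enriched footprints planted
  over the causal variants of upregulated responsive genes.

Every output is a deterministic function of ``SimConfig.seed``; each
generator stage draws from an independent seeded stream so stages can be
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, variant_stats
from .expression import ExpressionPair

__all__ = [
    "SimConfig",
    "generate_genotypes",
    "generate_gene_models",
    "generate_expression",
    "generate_footprints",
    "REQTL_CLASSES",
    "HEO_CLASSES",
    "UPREGULATED_CLASSES",
]

REQTL_CLASSES = (
    "reqtl_RefControl",
    "reqtl_RefHeat",
    "reqtl_AltControl",
    "reqtl_AltHeat",
)
HEO_CLASSES = ("heo_RefHeat", "heo_AltHeat")
#: classes whose more-responsive allele is upregulated under heat; these are
#: the genes whose causal variants receive planted heat-enriched footprints
UPREGULATED_CLASSES = ("reqtl_RefHeat", "reqtl_AltHeat") + HEO_CLASSES

# per-stage offsets for independent seeded streams
_STAGE_GENO, _STAGE_GENES, _STAGE_EXPR, _STAGE_FP = 11, 23, 37, 53


@dataclass
class SimConfig:
    """Study-scale parameters of the synthetic cohort.

    Defaults emulate the target study at desk scale: ~120 inbred genotypes
    from a handful of subpopulations, thousands of variants in LD blocks,
    and ~10^3 genes of which 30% carry cis effects, 5% are reQTLs (split
    over the four response categories), 2% are heat-expressed-only and 5%
    are consistently heat-upregulated.
    """

    n_samples: int = 120
    n_chromosomes: int = 3
    chrom_length_bp: int = 5_000_000
    n_variants: int = 6000
    indel_fraction: float = 0.09
    n_subpops: int = 4
    fst: float = 0.1
    residual_het_rate: float = 0.02
    ld_block_size: int = 20
    within_block_r: float = 0.9
    n_genes: int = 1200
    frac_cis: float = 0.3
    frac_reqtl: float = 0.05
    frac_heo: float = 0.02
    frac_consistent_up: float = 0.05
    n_trans_hotspots: int = 2
    targets_per_hotspot: int = 15
    nb_dispersion: float = 0.1
    libsize_range: tuple = (800_000, 1_200_000)
    n_hidden_factors: int = 3
    causal_placement: str = "any"  # any | promoter | genic
    causal_maf_min: float = 0.15
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "frac_cis": self.frac_cis,
            "frac_reqtl": self.frac_reqtl,
            "frac_heo": self.frac_heo,
            "frac_consistent_up": self.frac_consistent_up,
            "indel_fraction": self.indel_fraction,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        planted = (
            self.frac_cis + self.frac_reqtl + self.frac_heo + self.frac_consistent_up
        )
        if planted > 1:
            raise ValueError("planted class fractions sum above 1")
        if not 0 < self.fst < 0.5:
            raise ValueError("fst must be in (0, 0.5)")
        if self.n_variants < self.ld_block_size:
            raise ValueError("n_variants must be >= ld_block_size")
        if self.causal_placement not in ("any", "promoter", "genic"):
            raise ValueError(f"unknown causal_placement {self.causal_placement!r}")

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["libsize_range"] = list(d["libsize_range"])
        return d


def generate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Near-homozygous dosages in LD blocks under Balding-Nichols structure.

    Variants come in blocks of ``ld_block_size`` consecutive positions that
    share one allele frequency per subpopulation; within a block each
    sample's haplotype copies its block-seed draw, independently redrawn
    per variant with probability ``(1 - within_block_r) / 2``, which yields
    pairwise dosage correlation ~ within_block_r between block members and
    exact identity at within_block_r = 1.
    """
    rng = config.stage_rng(_STAGE_GENO)
    n, m = config.n_samples, config.n_variants
    n_blocks = int(np.ceil(m / config.ld_block_size))

    # subpopulation assignment, round-robin so sizes differ by <= 1
    subpop = np.arange(n) % config.n_subpops

    p_anc = rng.uniform(0.05, 0.95, size=n_blocks)
    F = config.fst
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p_sub = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, n_blocks))
    p_sub = np.clip(p_sub, 0.01, 0.99)

    block_of = np.arange(m) // config.ld_block_size
    switch = (1.0 - config.within_block_r) / 2.0
    z_seed = rng.uniform(size=(n, n_blocks))
    u = np.where(
        rng.uniform(size=(n, m)) < switch,
        rng.uniform(size=(n, m)),
        z_seed[:, block_of],
    )
    freq = p_sub[subpop][:, block_of]  # (n, m)
    hap = (u < freq).astype(float)
    dosage = 2.0 * hap
    het = rng.uniform(size=(n, m)) < config.residual_het_rate
    dosage[het] = 1.0

    # variant coordinates: even split over chromosomes, blocks never span two
    per_chrom = _split_even(m, config.n_chromosomes, config.ld_block_size)
    chroms, positions = [], []
    for c, nv in enumerate(per_chrom, start=1):
        pos = np.sort(
            rng.choice(np.arange(1, config.chrom_length_bp + 1), nv, replace=False)
        )
        chroms.extend([str(c)] * nv)
        positions.extend(pos.tolist())
    is_indel = rng.uniform(size=m) < config.indel_fraction
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + rng.integers(1, 4, size=m)) % 4]
    ins = bases[rng.integers(0, 4, size=m)]
    alt = np.where(is_indel, np.char.add(alt, ins), alt)
    variants = pd.DataFrame(
        {
            "id": [f"S{c}_{p}" for c, p in zip(chroms, positions)],
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "is_indel": is_indel,
        }
    )
    samples = [f"line{i:03d}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosage)


def _split_even(total: int, parts: int, multiple: int) -> list:
    """Split ``total`` into ``parts`` chunks, all but the last a multiple of
    ``multiple`` (so LD blocks never straddle a chromosome boundary)."""
    base = (total // parts // multiple) * multiple
    out = [base] * parts
    out[-1] = total - base * (parts - 1)
    return out


def generate_gene_models(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping gene models on a regular slot grid.

    Returns a DataFrame with 1-based inclusive [start, end], strand, and the
    strand-derived TSS/TTS.
    """
    rng = config.stage_rng(_STAGE_GENES)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    per_chrom[-1] += config.n_genes - sum(per_chrom)
    rows = []
    gid = 0
    for c, ng in enumerate(per_chrom, start=1):
        if ng == 0:
            continue
        slot = config.chrom_length_bp // ng
        max_len = slot - 5000  # room for 2-kb flanks plus spacing
        if max_len < 500:
            raise ValueError(
                f"cannot pack {ng} genes into a {config.chrom_length_bp}-bp chromosome"
            )
        lengths = rng.integers(min(2000, max_len), min(6000, max_len) + 1, size=ng)
        for k in range(ng):
            lo = k * slot + 2500
            hi = (k + 1) * slot - 2500 - lengths[k]
            start = int(rng.integers(lo, max(hi, lo + 1)))
            end = start + int(lengths[k]) - 1
            strand = "+" if rng.uniform() < 0.5 else "-"
            tss, tts = (start, end) if strand == "+" else (end, start)
            rows.append((f"g{gid:04d}", str(c), start, end, strand, tss, tts))
            gid += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tts"]
    )


def _eligible_causal(
    gene: pd.Series, variants: pd.DataFrame, maf: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Indices of variants usable as the gene's planted causal variant."""
    if config.causal_placement == "promoter":
        if gene.strand == "+":
            lo, hi = gene.tss - 2000, gene.tss - 1
        else:
            lo, hi = gene.tss + 1, gene.tss + 2000
    elif config.causal_placement == "genic":
        lo, hi = gene.start, gene.end
    else:
        lo, hi = gene.start - 2000, gene.end + 2000
    m = (
        (variants["chrom"].to_numpy() == gene.chrom)
        & (variants["pos"].to_numpy() >= lo)
        & (variants["pos"].to_numpy() <= hi)
        & (maf >= config.causal_maf_min)
    )
    return np.flatnonzero(m)


def generate_expression(
    G: GenotypeMatrix, genes: pd.DataFrame, config: SimConfig
) -> tuple[ExpressionPair, pd.DataFrame]:
    """Paired negative-binomial counts with planted effects and truth table.

    The log2 mean of gene g in sample i under condition c is

        eta = alpha_g + beta_g^(c) d_i + delta_g c + sum_k lambda_gk f_ki + g_i

    with counts ~ NB(mean = libsize/1e6 * 2^eta, dispersion nb_dispersion).
    Truth-table columns record each gene's class, causal variant, per-allele
    planted responses (L_ref, L_alt) and effect sizes.
    """
    rng = config.stage_rng(_STAGE_EXPR)
    n, ng = G.n_samples, len(genes)
    maf = variant_stats(G).maf

    elig = {g.gene_id: _eligible_causal(g, G.variants, maf, config) for g in genes.itertuples()}
    has_local = np.array([elig[g].size > 0 for g in genes["gene_id"]])

    n_cis = int(round(config.frac_cis * ng))
    n_reqtl = int(round(config.frac_reqtl * ng))
    n_heo = int(round(config.frac_heo * ng))
    n_cup = int(round(config.frac_consistent_up * ng))

    order = rng.permutation(ng)
    local_pool = [i for i in order if has_local[i]]
    free_pool = [i for i in order if not has_local[i]]
    need_local = n_cis + n_reqtl + n_heo
    if len(local_pool) < need_local:
        raise ValueError(
            f"only {len(local_pool)} genes have an eligible causal variant; "
            f"{need_local} needed"
        )
    classes = np.array(["null"] * ng, dtype=object)
    it = iter(local_pool)
    cis_idx = [next(it) for _ in range(n_cis)]
    reqtl_idx = [next(it) for _ in range(n_reqtl)]
    heo_idx = [next(it) for _ in range(n_heo)]
    rest = list(it) + free_pool
    cup_idx = rest[:n_cup]
    rest = rest[n_cup:]
    classes[cis_idx] = "cis_only"
    for j, gi in enumerate(reqtl_idx):
        classes[gi] = REQTL_CLASSES[j % len(REQTL_CLASSES)]
    for j, gi in enumerate(heo_idx):
        classes[gi] = HEO_CLASSES[j % len(HEO_CLASSES)]
    classes[cup_idx] = "consistent_up"

    # trans hotspots: one remote regulator variant, several target genes
    hotspot_of = np.full(ng, "", dtype=object)
    causal_idx = np.full(ng, -1, dtype=int)
    vpos = G.variants["pos"].to_numpy()
    vchrom = G.variants["chrom"].to_numpy()
    regulators = []
    for h in range(config.n_trans_hotspots):
        cand = np.flatnonzero(maf >= config.causal_maf_min)
        reg = int(rng.choice(cand))
        regulators.append(reg)
        remote = [
            gi
            for gi in rest
            if classes[gi] == "null"
            and (
                genes.iloc[gi].chrom != vchrom[reg]
                or min(
                    abs(genes.iloc[gi].start - vpos[reg]),
                    abs(genes.iloc[gi].end - vpos[reg]),
                )
                > 1_000_000
            )
        ]
        take = remote[: config.targets_per_hotspot]
        if len(take) < config.targets_per_hotspot:
            raise ValueError("not enough remote null genes for hotspot targets")
        for gi in take:
            classes[gi] = "trans_target"
            causal_idx[gi] = reg
            hotspot_of[gi] = f"hotspot{h}"

    # per-gene parameters
    alpha = rng.uniform(1.0, 8.0, size=ng)
    beta0 = np.zeros(ng)
    beta1 = np.zeros(ng)
    delta = np.zeros(ng)
    L_ref = np.full(ng, np.nan)
    L_alt = np.full(ng, np.nan)

    def pick_variant(gi):
        causal_idx[gi] = int(rng.choice(elig[genes.iloc[gi].gene_id]))

    for gi in cis_idx:
        pick_variant(gi)
        beta0[gi] = beta1[gi] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)

    for gi in reqtl_idx:
        pick_variant(gi)
        # moderate baseline: strongly responding genes at the top of the
        # expression range would dominate the (desk-scale) heat library and
        # impose a spurious compositional down-shift on every other gene
        alpha[gi] = rng.uniform(1.0, 4.5)
        klass = classes[gi]
        theta_mag = rng.uniform(1.15, 1.6)
        bump = rng.uniform(0.0, 0.5)
        small = rng.uniform(0.0, 0.3)
        s = 1.0 if klass.endswith("Heat") else -1.0
        L_big = s * (2.0 * theta_mag + bump)
        L_small = s * small
        if klass.startswith("reqtl_Ref"):
            L_ref[gi], L_alt[gi] = L_big, L_small
        else:
            L_ref[gi], L_alt[gi] = L_small, L_big
        delta[gi] = L_ref[gi]
        beta0[gi] = rng.uniform(-0.4, 0.4)
        beta1[gi] = beta0[gi] + (L_alt[gi] - L_ref[gi]) / 2.0

    for gi in heo_idx:
        pick_variant(gi)
        # silent under control (expected count << 1 so CPM < 1 in nearly all
        # genotypes regardless of realized library size), strongly activated
        # under heat with an allele-dependent level
        alpha[gi] = rng.uniform(-6.0, -4.5)
        delta[gi] = rng.uniform(7.0, 9.0)
        mag = rng.uniform(0.75, 1.25)
        beta1[gi] = mag if classes[gi] == "heo_AltHeat" else -mag
        L_ref[gi] = delta[gi]
        L_alt[gi] = delta[gi] + 2.0 * beta1[gi]

    for gi in cup_idx:
        alpha[gi] = rng.uniform(1.0, 4.5)  # same compositional-balance cap
        delta[gi] = rng.uniform(2.0, 4.0)

    # remote regulators must survive both the structure-PC residualization and
    # the genome-wide trans BH stratum, so their planted effects are strong
    for gi in np.flatnonzero(classes == "trans_target"):
        beta0[gi] = beta1[gi] = rng.choice([-1.0, 1.0]) * rng.uniform(1.25, 2.0)

    # hidden factors with sparse loadings, per-genotype random intercept
    factors = rng.standard_normal((config.n_hidden_factors, n))
    loadings = np.zeros((ng, config.n_hidden_factors))
    if config.n_hidden_factors:
        affected = rng.uniform(size=(ng, config.n_hidden_factors)) < 0.30
        loadings[affected] = rng.normal(0.0, 0.5, size=int(affected.sum()))
    g_intercept = rng.normal(0.0, 0.2, size=(ng, n))

    d_causal = np.zeros((ng, n))
    planted = causal_idx >= 0
    d_causal[planted] = G.dosage[:, causal_idx[planted]].T
    d_causal = np.nan_to_num(d_causal, nan=1.0)  # residual-het missing never occurs

    lib = rng.uniform(*config.libsize_range, size=(2, n))
    base = alpha[:, None] + loadings @ factors + g_intercept
    counts = {}
    for c, cond in enumerate(("control", "heat")):
        beta_c = beta0 if c == 0 else beta1
        eta = base + beta_c[:, None] * d_causal + delta[:, None] * c
        mu = (lib[c][None, :] / 1e6) * np.exp(np.log(2.0) * eta)
        if config.nb_dispersion < 1e-8:
            counts[cond] = rng.poisson(mu).astype(float)
        else:
            nb_n = 1.0 / config.nb_dispersion
            counts[cond] = rng.negative_binomial(
                nb_n, nb_n / (nb_n + mu)
            ).astype(float)

    pair = ExpressionPair(
        genes["gene_id"].tolist(), list(G.samples), counts["control"], counts["heat"]
    )
    vid = G.variants["id"].to_numpy()
    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "class": classes,
            "causal_variant_id": [vid[i] if i >= 0 else "" for i in causal_idx],
            "beta_control": beta0,
            "beta_heat": beta1,
            "activation_delta": delta,
            "L_ref": L_ref,
            "L_alt": L_alt,
            "hotspot_id": hotspot_of,
        }
    )
    return pair, truth


def generate_footprints(
    truth: pd.DataFrame,
    genes: pd.DataFrame,
    G: GenotypeMatrix,
    config: SimConfig,
    p_true: float = 0.8,
    background_per_gene: int = 2,
) -> pd.DataFrame:
    """TF-footprint intervals (BED-style, 0-based half-open) with statuses.

    Background footprints (~34-bp median width) are scattered near every
    gene's TSS with mostly ``stable`` status; for each upregulated
    responsive gene (heat-responding reQTL or heo class), with probability
    ``p_true`` a ``heat_enriched`` footprint is planted covering its causal
    variant. Three control + three heat replicate counts consistent with
    each status are attached.
    """
    rng = config.stage_rng(_STAGE_FP)
    pos_of = dict(zip(G.variants["id"], G.variants["pos"]))
    chrom_of = dict(zip(G.variants["id"], G.variants["chrom"]))
    truth_by_gene = truth.set_index("gene_id")
    rows = []

    def add(chrom, start, end, status, intended_gene):
        start = max(0, int(start))
        end = min(int(end), config.chrom_length_bp)
        if end <= start:
            return
        base = rng.uniform(20, 120)
        fold = {"stable": 1.0, "heat_enriched": 4.0, "heat_depleted": 0.25}[status]
        ctrl = rng.poisson(base, size=3)
        heat = rng.poisson(base * fold, size=3)
        rows.append((chrom, start, end, status, intended_gene, *ctrl, *heat))

    statuses = np.array(["stable", "heat_enriched", "heat_depleted"])
    for g in genes.itertuples():
        tss0 = g.tss - 1  # 0-based
        for _ in range(background_per_gene):
            width = max(16, int(round(rng.normal(34, 8))))
            offset = int(rng.integers(-1500, 1501))
            status = str(rng.choice(statuses, p=[0.90, 0.05, 0.05]))
            add(g.chrom, tss0 + offset, tss0 + offset + width, status, g.gene_id)
        tinfo = truth_by_gene.loc[g.gene_id]
        if tinfo["class"] in UPREGULATED_CLASSES and tinfo["causal_variant_id"]:
            if rng.uniform() < p_true:
                width = max(20, int(round(rng.normal(34, 8))))
                vpos0 = pos_of[tinfo["causal_variant_id"]] - 1
                lead = int(rng.integers(2, width - 2))
                add(
                    chrom_of[tinfo["causal_variant_id"]],
                    vpos0 - lead,
                    vpos0 - lead + width,
                    "heat_enriched",
                    g.gene_id,
                )
        elif tinfo["class"] == "consistent_up":
            # heat-activated genes gain promoter occupancy (the HSP pattern):
            # a heat-enriched footprint upstream of the TSS, no causal variant
            if rng.uniform() < p_true:
                width = max(20, int(round(rng.normal(34, 8))))
                offset = int(rng.integers(50, 1500))
                start = tss0 - offset - width if g.strand == "+" else tss0 + offset
                add(g.chrom, start, start + width, "heat_enriched", g.gene_id)

    fp = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "status", "intended_gene",
            "control_1", "control_2", "control_3", "heat_1", "heat_2", "heat_3",
        ],
    )
    fp = fp.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    fp.insert(0, "footprint_id", [f"fp{i:05d}" for i in range(len(fp))])
    return fp
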