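"""Readers and writers for the ingestion-boundary formats.

Stage outputs are plain TSV throughout; VCF (genotypes), GFF3 (gene models)
and BED6+ (footprints) are supported at the package boundary. Genotype VCFs
are minimal VCFv4.2 with GT fields and biallelic records; reading uses
cyvcf2 when it is importable and a small text parser otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .expression import ExpressionPair

__all__ = [
    "write_vcf", "read_vcf",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_genes_tsv", "read_genes_tsv", "write_gff3",
    "write_counts_tsv", "read_expression_pair",
    "write_footprints_bed", "read_footprints_bed",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path, contig_length: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.variants["chrom"]):
            if contig_length:
                fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, v in enumerate(G.variants.itertuples()):
            gts = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in G.dosage[:, j]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_vcf_text(path) -> GenotypeMatrix:
    rows, dosages, samples = [], [], None
    code = {"0/0": 0.0, "0|0": 0.0, "0/1": 1.0, "1/0": 1.0, "0|1": 1.0,
            "1|0": 1.0, "1/1": 2.0, "1|1": 2.0}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[:5]
            gt_field = parts[8].split(":").index("GT")
            calls = [p.split(":")[gt_field] for p in parts[9:]]
            dosages.append([code.get(c, np.nan) for c in calls])
            rows.append(
                (vid, chrom, int(pos), ref, alt, len(ref) != 1 or len(alt) != 1)
            )
    variants = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "ref", "alt", "is_indel"]
    )
    return GenotypeMatrix(samples, variants, np.array(dosages, dtype=float).T)


def read_vcf(G_path) -> GenotypeMatrix:
    """Load a biallelic GT-only VCF into a GenotypeMatrix."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(G_path)
    vcf = VCF(str(G_path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for rec in vcf:
        gt = np.asarray(rec.gt_types, dtype=float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        dosages.append(gt)
        rows.append(
            (
                rec.ID or f"S{rec.CHROM}_{rec.POS}",
                rec.CHROM,
                rec.POS,
                rec.REF,
                rec.ALT[0],
                len(rec.REF) != 1 or len(rec.ALT[0]) != 1,
            )
        )
    variants = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "ref", "alt", "is_indel"]
    )
    return GenotypeMatrix(samples, variants, np.array(dosages, dtype=float).T)


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    df = G.variants.copy()
    dos = pd.DataFrame(G.dosage.T, columns=G.samples)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "ref", "alt", "is_indel"]
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        samples, df[meta_cols], df[samples].to_numpy(dtype=float).T
    )


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "tss" not in genes.columns:
        plus = genes["strand"] == "+"
        genes["tss"] = np.where(plus, genes["start"], genes["end"])
        genes["tts"] = np.where(plus, genes["end"], genes["start"])
    return genes


def write_gff3(genes: pd.DataFrame, path, source: str = "reqtlkit") -> None:
    """1-based inclusive gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def write_counts_tsv(counts: np.ndarray, genes, samples, path) -> None:
    pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples).to_csv(
        path, sep="\t"
    )


def read_expression_pair(control_path, heat_path) -> ExpressionPair:
    c = pd.read_csv(control_path, sep="\t", index_col=0)
    h = pd.read_csv(heat_path, sep="\t", index_col=0)
    if not (c.index.equals(h.index) and c.columns.equals(h.columns)):
        raise ValueError("control and heat matrices must share genes and samples")
    return ExpressionPair(
        c.index.tolist(), c.columns.tolist(), c.to_numpy(), h.to_numpy()
    )


def write_footprints_bed(fp: pd.DataFrame, path) -> None:
    """BED6+ with status, fdr and six replicate-count columns."""
    out = fp.copy()
    cols = ["chrom", "start", "end"]
    out["name"] = out.get("footprint_id", pd.Series(range(len(out))).map("fp{:05d}".format))
    out["score"] = 0
    out["strand"] = "."
    extra = [c for c in ("status", "fdr", "intended_gene", "control_1", "control_2",
                         "control_3", "heat_1", "heat_2", "heat_3") if c in out.columns]
    out[cols + ["name", "score", "strand"] + extra].to_csv(
        path, sep="\t", index=False, header=True
    )


def read_footprints_bed(path) -> pd.DataFrame:
    fp = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fp = fp.rename(columns={"name": "footprint_id"})
    return fp.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
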