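"""Readers and writers for the pipeline's external formats.

TSV for counts / sample metadata / result tables, VCF 4.x for SNP genotypes
(via cyvcf2), BED6 or GFF3 for gene intervals, and the 1-based-VCF to
0-based-half-open interval conversion used to assign SNPs to gene regions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    validate_counts,
    validate_deg_list,
    validate_gene_models,
    validate_samples,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample raw count TSV (first column gene ids, header samples)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as e:
        raise FormatError(f"malformed count TSV {path}: {e}") from e
    df.index.name = "gene_id"
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as e:
        raise FormatError(f"non-integer counts in {path}: {e}") from e
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype_id": str})
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample float matrix TSV (normalized expression etc.)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df.astype(float)


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_deg_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return validate_deg_list(df)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into an ALT-dosage matrix.

    Indels and multi-allelic records are dropped (logged with a count);
    genotypes are coded 0/0 -> 0, 0/1 or 0|1 -> 1, 1/1 -> 2, ./. -> missing.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    if "ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    accessions = list(vcf.samples)
    rows, dosages = [], []
    n_dropped = 0
    for i, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_dropped += 1
                continue
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            gt = np.asarray(v.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
            dosages.append(gt)
        except Exception as e:
            raise FormatError(f"{path}: malformed record #{i + 1}: {e}") from e
    if n_dropped:
        log.info("read_vcf(%s): dropped %d indel/multi-allelic records", path, n_dropped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.vstack(dosages)
        if dosages
        else np.empty((0, len(accessions)), dtype=np.int8)
    )
    return GenotypeMatrix(sites=sites, accessions=accessions, dosage=dosage)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes (unphased)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(geno.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accessions)
            + "\n"
        )
        for i, site in enumerate(geno.sites.itertuples(index=False)):
            gts = "\t".join(code[int(d)] for d in geno.dosage[i])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# gene intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (>=4 columns; 0-based half-open natively)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise FormatError(f"{path}: BED needs >= 4 columns (chrom start end name)")
    names = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    genes = df[["gene_id", "chrom", "start", "end"]].copy()
    genes["strand"] = df["strand"] if "strand" in df.columns else "."
    return validate_gene_models(genes)


def write_bed(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes.get("strand", ".")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3; 1-based closed intervals become half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand or "."))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return validate_gene_models(genes)


def read_gene_models(path) -> pd.DataFrame:
    """Dispatch on file suffix: .bed -> BED, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed(path)
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    raise FormatError(f"unrecognized gene interval format: {path}")


def assign_sites_to_genes(geno: GenotypeMatrix, genes: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map each gene to the indices of SNP sites falling in its interval.

    VCF positions are 1-based, gene intervals 0-based half-open, so a site at
    position p lies in gene [start, end) iff p - 1 is in [start, end), i.e.
    start < p <= end. A site inside two overlapping genes is assigned to both;
    genes with no sites map to an empty array.
    """
    out: dict[str, np.ndarray] = {}
    pos_by_chrom = {
        chrom: (grp["pos"].to_numpy(), grp.index.to_numpy())
        for chrom, grp in geno.sites.groupby("chrom", sort=False)
    }
    for g in genes.itertuples(index=False):
        pos, idx = pos_by_chrom.get(g.chrom, (np.empty(0, dtype=int), np.empty(0, dtype=int)))
        lo = np.searchsorted(pos, g.start, side="right")  # first pos > start
        hi = np.searchsorted(pos, g.end, side="right")  # first pos > end
        out[g.gene_id] = idx[lo:hi]
    return out
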