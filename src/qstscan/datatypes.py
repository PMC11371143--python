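"""Shared domain types and validation for the tetraploid-wheat expression/popgen pipeline.

The pipeline works on four substrates: a gene x sample count matrix, a sample
metadata table mapping samples to genotype / taxon / nitrogen level / replicate,
a biallelic SNP genotype matrix (ALT-allele dosage per accession), and gene
interval models. Tabular data are plain pandas DataFrames validated by the
functions here; the genotype matrix is a small dataclass wrapping a numpy
dosage array plus a site table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxa in domestication order: wild emmer -> emmer -> durum wheat.
TAXA = ("wild_emmer", "emmer", "durum")

#: Nitrogen treatment levels.
NITROGEN_LEVELS = ("low", "high")

#: Pairwise taxon comparisons; primary domestication, secondary, cumulative.
PAIRS: dict[str, tuple[str, str]] = {
    "wild_vs_emmer": ("wild_emmer", "emmer"),
    "emmer_vs_durum": ("emmer", "durum"),
    "wild_vs_durum": ("wild_emmer", "durum"),
}

#: The six (pair, nitrogen) scan comparisons.
COMPARISONS = tuple((pair, n) for pair in PAIRS for n in NITROGEN_LEVELS)

SAMPLE_COLUMNS = ("sample_id", "genotype_id", "taxon", "nitrogen", "replicate")

#: Missing dosage sentinel in GenotypeMatrix.dosage.
MISSING = -1


class FormatError(ValueError):
    """Raised when an input file or table violates the format contract."""


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table.

    Requires columns sample_id, genotype_id, taxon, nitrogen, replicate;
    sample ids unique; taxa and nitrogen levels drawn from the known sets;
    each genotype mapped to exactly one taxon.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample ids: {dups}")
    bad_taxa = set(samples["taxon"]) - set(TAXA)
    if bad_taxa:
        raise FormatError(f"unknown taxa {sorted(bad_taxa)}; expected {TAXA}")
    bad_n = set(samples["nitrogen"]) - set(NITROGEN_LEVELS)
    if bad_n:
        raise FormatError(f"unknown nitrogen levels {sorted(bad_n)}")
    taxon_per_geno = samples.groupby("genotype_id")["taxon"].nunique()
    if (taxon_per_geno > 1).any():
        bad = taxon_per_geno[taxon_per_geno > 1].index.tolist()
        raise FormatError(f"genotypes mapped to more than one taxon: {bad}")
    if (samples["replicate"].astype(int) < 1).any():
        raise FormatError("replicate numbers must be positive integers")
    return samples


def validate_counts(counts: pd.DataFrame, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a gene x sample raw count matrix (genes on rows)."""
    if counts.index.duplicated().any():
        raise FormatError("duplicated gene ids in count matrix")
    if counts.columns.duplicated().any():
        raise FormatError("duplicated sample ids in count matrix")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            raise FormatError("count matrix must contain integers")
    if (arr < 0).any():
        raise FormatError("count matrix contains negative entries")
    if samples is not None:
        extra = set(counts.columns) - set(samples["sample_id"])
        if extra:
            raise FormatError(f"count columns not in sample table: {sorted(extra)}")
    return counts


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes as ALT-allele dosage (0/1/2, -1 = missing).

    sites: DataFrame with columns chrom, pos (1-based), ref, alt, one row per
    SNP, positions strictly increasing within each chromosome.
    dosage: int8 array of shape (n_sites, n_accessions).
    """

    sites: pd.DataFrame
    accessions: list[str] = field(default_factory=list)
    dosage: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int8))

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sites), len(self.accessions)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.accessions)} accessions"
            )
        ok = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not ok.all():
            raise FormatError("dosage values must be 0, 1, 2 or -1 (missing)")
        if (self.sites["pos"].to_numpy() < 1).any():
            raise FormatError("VCF positions are 1-based; pos must be >= 1")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError("positions must be strictly increasing within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to sites at integer indices `idx` (kept in given order)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            accessions=list(self.accessions),
            dosage=self.dosage[idx],
        )

    def accession_indices(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"accession {e.args[0]!r} not in genotype matrix") from e


def validate_gene_models(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate gene interval models (0-based half-open, BED convention)."""
    for c in ("gene_id", "chrom", "start", "end"):
        if c not in genes.columns:
            raise FormatError(f"gene model table missing column {c!r}")
    if "strand" not in genes.columns:
        genes = genes.assign(strand=".")
    if genes["gene_id"].duplicated().any():
        raise FormatError("duplicated gene ids in gene models")
    if (genes["start"].to_numpy() >= genes["end"].to_numpy()).any():
        raise FormatError("gene intervals must satisfy start < end")
    if (genes["start"].to_numpy() < 0).any():
        raise FormatError("gene starts must be >= 0")
    return genes


def validate_deg_list(degs: pd.DataFrame) -> pd.DataFrame:
    """Validate a differential-expression call table.

    Direction must be consistent with the sign of log2fc and padj in [0, 1].
    """
    for c in ("gene_id", "log2fc", "padj", "direction"):
        if c not in degs.columns:
            raise FormatError(f"DEG list missing column {c!r}")
    if ((degs["padj"] < 0) | (degs["padj"] > 1)).any():
        raise FormatError("padj values must lie in [0, 1]")
    up = degs["log2fc"] > 0
    want = np.where(up, "up", "down")
    if (degs["direction"].to_numpy() != want).any():
        raise FormatError("direction must be 'up' iff log2fc > 0")
    return degs
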