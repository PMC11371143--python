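"""Population-genetic statistics on the hard-genotype dosage matrix.

Per-site estimators with closed forms: unbiased average pairwise difference
for pi (2*p*q * m/(m-1) over the m non-missing allele copies at a site),
Watterson's theta from the segregating-site count, and the Hudson/Bhatia
two-population Fst decomposition into a numerator A (between-population
variance, sample-size corrected) and denominator B (total expected variance).
Per-gene weighted Fst is the ratio of summed As to summed Bs over the gene's
sites — a ratio of sums, never a mean of per-site ratios. Structure is
visualized by classical MDS of an allele-sharing distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, PAIRS, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele counts and filters
# ---------------------------------------------------------------------------

def allele_counts(
    geno: GenotypeMatrix, accession_idx: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt_allele_count, non_missing_allele_copies) over a subset."""
    d = geno.dosage if accession_idx is None else geno.dosage[:, accession_idx]
    ok = d != MISSING
    alt = np.where(ok, d, 0).sum(axis=1)
    m = 2 * ok.sum(axis=1)
    return alt.astype(float), m.astype(float)


def filter_snps(
    geno: GenotypeMatrix, max_missing: float = 0.5, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Drop sites with missing fraction > max_missing or pooled MAF < min_maf."""
    miss_frac = (geno.dosage == MISSING).mean(axis=1)
    alt, m = allele_counts(geno)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / np.where(m > 0, m, 1.0), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_frac <= max_missing) & (maf >= min_maf)
    log.info("filter_snps: %d of %d sites retained", int(keep.sum()), geno.n_sites)
    return geno.take_sites(np.flatnonzero(keep))


def partition_snps(geno: GenotypeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Private/shared partition over the 7 non-empty taxon subsets.

    A site is "present" in a taxon iff it is polymorphic (both alleles seen)
    within that taxon's accessions. Returns per-site presence flags and the
    Venn cell label ("+"-joined taxa, empty string if absent everywhere).
    """
    taxon_of = samples.drop_duplicates("genotype_id").set_index("genotype_id")["taxon"]
    taxa = [t for t in ("wild_emmer", "emmer", "durum") if t in set(taxon_of)]
    presence = {}
    for taxon in taxa:
        acc = [a for a in geno.accessions if taxon_of.get(a) == taxon]
        idx = geno.accession_indices(acc)
        alt, m = allele_counts(geno, idx)
        presence[taxon] = (alt > 0) & (alt < m)
    out = geno.sites[["chrom", "pos"]].copy()
    for taxon in taxa:
        out[taxon] = presence[taxon]
    out["cell"] = [
        "+".join(t for t in taxa if out[t].iloc[i]) for i in range(len(out))
    ]
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def pi(
    geno: GenotypeMatrix,
    total_sites: int,
    accession_idx: np.ndarray | None = None,
) -> float:
    """Nucleotide diversity: mean pairwise difference summed over polymorphic
    sites, divided by the total number of surveyed sites.

    Per site with m >= 2 non-missing allele copies and ALT frequency p, the
    unbiased average pairwise difference is 2*p*(1-p) * m/(m-1).
    """
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    alt, m = allele_counts(geno, accession_idx)
    usable = m >= 2
    p = alt[usable] / m[usable]
    per_site = 2.0 * p * (1.0 - p) * m[usable] / (m[usable] - 1.0)
    return float(per_site.sum() / total_sites)


def theta_w(n_alleles: int, segregating_sites: int, total_sites: int) -> float:
    """Watterson's theta per site: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n_alleles < 2:
        raise ValueError("need >= 2 allele copies")
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    a_n = np.sum(1.0 / np.arange(1, n_alleles))
    return float(segregating_sites / (a_n * total_sites))


@dataclass
class DiversityStats:
    taxon: str
    pi: float
    theta_w: float
    segregating_sites: int
    total_sites: int


def diversity_stats(
    geno: GenotypeMatrix, samples: pd.DataFrame, taxon: str, total_sites: int
) -> DiversityStats:
    """Per-taxon pi and Watterson theta.

    theta uses n_alleles = 2 x (accessions of the taxon); missing calls are
    handled per site inside pi and the segregating-site count.
    """
    taxon_of = samples.drop_duplicates("genotype_id").set_index("genotype_id")["taxon"]
    acc = [a for a in geno.accessions if taxon_of.get(a) == taxon]
    if len(acc) < 1:
        raise ValueError(f"no accessions for taxon {taxon!r}")
    idx = geno.accession_indices(acc)
    alt, m = allele_counts(geno, idx)
    seg = int(np.sum((alt > 0) & (alt < m)))
    return DiversityStats(
        taxon=taxon,
        pi=pi(geno, total_sites, idx),
        theta_w=theta_w(2 * len(acc), seg, total_sites),
        segregating_sites=seg,
        total_sites=total_sites,
    )


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def fst_site(p1: float, n1: float, p2: float, n2: float) -> tuple[float, float]:
    """Hudson/Bhatia per-site components.

    A = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)  (between-pop variance)
    B = p1(1-p2) + p2(1-p1)                            (total expected variance)
    n1, n2 count non-missing allele copies and must both be >= 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 allele copies per population")
    a = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    b = p1 * (1 - p2) + p2 * (1 - p1)
    return a, b


def _pair_freqs(geno: GenotypeMatrix, samples: pd.DataFrame, pair: str):
    taxon_of = samples.drop_duplicates("genotype_id").set_index("genotype_id")["taxon"]
    t1, t2 = PAIRS[pair]
    idx1 = geno.accession_indices([a for a in geno.accessions if taxon_of.get(a) == t1])
    idx2 = geno.accession_indices([a for a in geno.accessions if taxon_of.get(a) == t2])
    alt1, m1 = allele_counts(geno, idx1)
    alt2, m2 = allele_counts(geno, idx2)
    return alt1, m1, alt2, m2


def _fst_components(alt1, m1, alt2, m2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site (A, B, usable); sites with < 2 copies in either
    population are flagged unusable (skipped by callers, logged)."""
    usable = (m1 >= 2) & (m2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(m1 > 0, alt1 / np.where(m1 > 0, m1, 1.0), 0.0)
        p2 = np.where(m2 > 0, alt2 / np.where(m2 > 0, m2, 1.0), 0.0)
        a = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(m1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(m2 - 1, 1)
        )
        b = p1 * (1 - p2) + p2 * (1 - p1)
    return a, b, usable


def fst_gene(
    geno: GenotypeMatrix,
    samples: pd.DataFrame,
    gene_sites: dict[str, np.ndarray],
    pair: str,
) -> pd.DataFrame:
    """Per-gene weighted Fst = sum(A)/sum(B) over the gene's usable sites.

    Genes with no usable sites or sum(B) = 0 get fst = NaN; negative values
    are reported as-is (truncation happens only at the scan stage).
    """
    alt1, m1, alt2, m2 = _pair_freqs(geno, samples, pair)
    a, b, usable = _fst_components(alt1, m1, alt2, m2)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("fst_gene(%s): %d sites skipped (<2 allele copies)", pair, n_skipped)
    rows = []
    for gene_id, idx in gene_sites.items():
        idx = np.asarray(idx, dtype=int)
        use = idx[usable[idx]] if len(idx) else idx
        sum_a = float(a[use].sum()) if len(use) else 0.0
        sum_b = float(b[use].sum()) if len(use) else 0.0
        fst = sum_a / sum_b if sum_b > 0 else float("nan")
        rows.append((gene_id, pair, fst, sum_a, sum_b, len(use)))
    return pd.DataFrame(
        rows, columns=["gene_id", "pair", "fst", "sum_A", "sum_B", "n_sites"]
    )


def fst_genome(geno: GenotypeMatrix, samples: pd.DataFrame, pair: str) -> float:
    """Genome-wide weighted Fst: ratio of summed As to summed Bs over all sites."""
    alt1, m1, alt2, m2 = _pair_freqs(geno, samples, pair)
    a, b, usable = _fst_components(alt1, m1, alt2, m2)
    sb = b[usable].sum()
    if sb == 0:
        return float("nan")
    return float(a[usable].sum() / sb)


def fst_table(
    geno: GenotypeMatrix, samples: pd.DataFrame, gene_sites: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-gene weighted Fst for all three taxon pairs."""
    return pd.concat(
        [fst_gene(geno, samples, gene_sites, pair) for pair in PAIRS],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# thinning and PCA
# ---------------------------------------------------------------------------

def thin_snps(geno: GenotypeMatrix, window: int = 500_000) -> GenotypeMatrix:
    """Keep the first SNP per non-overlapping window (anchored at position 1)
    per chromosome."""
    sites = geno.sites
    win = (sites["pos"].to_numpy() - 1) // window
    keep = ~pd.DataFrame({"chrom": sites["chrom"], "win": win}).duplicated().to_numpy()
    return geno.take_sites(np.flatnonzero(keep))


def genotype_pca(geno: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Classical MDS of the allele-sharing distance matrix.

    Distance between accessions i, j is mean(|d_i - d_j|) / 2 over sites where
    both are non-missing; coordinates come from double-centering the squared
    distance matrix and eigendecomposition (deterministic up to axis sign).
    """
    d = geno.dosage.astype(float)
    d[geno.dosage == MISSING] = np.nan
    n = geno.n_accessions
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[:, i : i + 1] - d[:, i:])  # upper triangle, vectorized
        shared = np.sum(~np.isnan(diff), axis=0)
        if np.any(shared == 0):
            j = i + int(np.flatnonzero(shared == 0)[0])
            raise ValueError(
                f"accessions {geno.accessions[i]!r} and {geno.accessions[j]!r} "
                "share no genotyped sites"
            )
        dist[i, i:] = np.nanmean(diff, axis=0) / 2.0
    dist = np.maximum(dist, dist.T)

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    k = min(n_components, int(pos.sum()))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    out = pd.DataFrame(
        coords, index=pd.Index(geno.accessions, name="genotype_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    out.attrs["eigenvalues"] = eigval[:k]
    return out
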