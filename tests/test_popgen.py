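import itertools

import numpy as np
import pandas as pd
import pytest

from qstscan import popgen
from qstscan.datatypes import MISSING, GenotypeMatrix
from qstscan.sim import SimConfig, make_sample_table, simulate_genotypes


def _geno(dosage, positions=None, chrom="chr1", accessions=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_acc = dosage.shape
    positions = positions if positions is not None else np.arange(1, n_sites + 1)
    accessions = accessions or [f"a{i}" for i in range(n_acc)]
    sites = pd.DataFrame({"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"})
    return GenotypeMatrix(sites=sites, accessions=accessions, dosage=dosage)


def _samples(taxon_of):
    return pd.DataFrame(
        {
            "sample_id": [f"{g}_low_1" for g in taxon_of],
            "genotype_id": list(taxon_of),
            "taxon": [taxon_of[g] for g in taxon_of],
            "nitrogen": "low",
            "replicate": 1,
        }
    )


# ---------------------------------------------------------------------------
# filters and partitions
# ---------------------------------------------------------------------------

def test_filter_snps_rules():
    n_acc = 32
    dosage = np.zeros((3, n_acc), dtype=np.int8)
    dosage[0, :17] = MISSING  # 53% missing -> dropped
    dosage[0, 17] = 1
    dosage[1, 0] = 1  # 1 ALT of 64 alleles, MAF 1.6% -> retained
    # site 2 monomorphic -> dropped
    geno = _geno(dosage)
    out = popgen.filter_snps(geno, max_missing=0.5, min_maf=0.01)
    assert list(out.sites["pos"]) == [2]


def test_partition_private_and_shared():
    taxon_of = {"w1": "wild_emmer", "w2": "wild_emmer",
                "e1": "emmer", "e2": "emmer", "d1": "durum", "d2": "durum"}
    samples = _samples(taxon_of)
    dosage = np.array(
        [
            [0, 0, 0, 0, 0, 1],  # polymorphic only in durum
            [0, 1, 0, 1, 0, 1],  # polymorphic in all three
            [0, 1, 0, 1, 2, 2],  # wild+emmer only (durum fixed ALT)
            [0, 0, 0, 0, 0, 0],  # absent everywhere
        ],
        dtype=np.int8,
    )
    part = popgen.partition_snps(
        _geno(dosage, accessions=list(taxon_of)), samples
    )
    assert part.loc[0, "cell"] == "durum"
    assert part.loc[1, "cell"] == "wild_emmer+emmer+durum"
    assert part.loc[2, "cell"] == "wild_emmer+emmer"
    assert part.loc[3, "cell"] == ""
    # disjoint and exhaustive: each site in exactly one cell; counts add up
    present = part["cell"] != ""
    assert present.sum() == 3


def test_partition_conservation_on_random_matrix():
    cfg = SimConfig(n_genes=40, n_sites_per_gene=5, missing_rate=0.05, seed=21)
    geno = simulate_genotypes(cfg)
    samples = make_sample_table(cfg)
    part = popgen.partition_snps(geno, samples)
    n_present = (part[["wild_emmer", "emmer", "durum"]].any(axis=1)).sum()
    assert (part["cell"] != "").sum() == n_present
    assert part["cell"].value_counts().drop("", errors="ignore").sum() == n_present


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_pi_two_sequence_definition():
    """Two haploid sequences (one het accession) differing at 2 of 100 sites
    give pi = 0.02."""
    dosage = np.array([[1], [1]], dtype=np.int8)  # 2 het sites of 100 surveyed
    assert popgen.pi(_geno(dosage), total_sites=100) == pytest.approx(0.02)


def test_pi_monomorphic_is_zero():
    assert popgen.pi(_geno(np.zeros((5, 4), dtype=np.int8)), 100) == 0.0


def test_pi_matches_brute_force_allele_pairs():
    """pi agrees to 1e-12 with the all-pairs Hamming average over expanded
    allele sequences on a 5-accession toy."""
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
    geno = _geno(dosage)
    L = 30
    # expand to 10 allele sequences; phase is irrelevant to the average
    alleles = np.zeros((L, 10), dtype=int)
    for j in range(5):
        for s in range(L):
            d = dosage[s, j]
            alleles[s, 2 * j] = 1 if d >= 1 else 0
            alleles[s, 2 * j + 1] = 1 if d == 2 else 0
    total = sum(
        np.sum(alleles[:, i] != alleles[:, j])
        for i, j in itertools.combinations(range(10), 2)
    )
    n_pairs = 10 * 9 / 2
    brute = total / n_pairs / L
    assert popgen.pi(geno, L) == pytest.approx(brute, abs=1e-12)


def test_theta_w_closed_forms():
    assert popgen.theta_w(4, 3, 100) == pytest.approx(3 / ((1 + 1 / 2 + 1 / 3) * 100))
    assert popgen.theta_w(2, 5, 100) == pytest.approx(0.05)  # a_1 = 1: theta = S/L
    assert popgen.theta_w(10, 0, 100) == 0.0
    with pytest.raises(ValueError):
        popgen.theta_w(1, 1, 100)
    with pytest.raises(ValueError):
        popgen.theta_w(4, 1, 0)


def test_diversity_invariant_to_allele_relabeling():
    rng = np.random.default_rng(2)
    dosage = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
    geno = _geno(dosage)
    flipped = _geno((2 - dosage).astype(np.int8))
    assert popgen.pi(geno, 200) == pytest.approx(popgen.pi(flipped, 200), abs=1e-15)


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def test_fst_site_closed_forms():
    a, b = popgen.fst_site(1.0, 10, 0.0, 10)
    assert (a, b) == (1.0, 1.0)
    a, b = popgen.fst_site(0.5, 10, 0.5, 10)
    assert a == pytest.approx(-1 / 18)
    assert b == pytest.approx(0.5)
    a, _ = popgen.fst_site(0.3, 10_000, 0.3, 10_000)
    assert abs(a) < 1e-4
    with pytest.raises(ValueError):
        popgen.fst_site(0.5, 1, 0.5, 10)


def test_fst_gene_ratio_of_sums_not_mean_of_ratios():
    """Two sites with (A,B) = (1,1) and (-0.05,0.5): the weighted estimate is
    0.95/1.5, which differs from the mean of per-site ratios."""
    taxon_of = {"w1": "wild_emmer", "w2": "wild_emmer",
                "e1": "emmer", "e2": "emmer"}
    samples = _samples(taxon_of)
    # site0: fixed difference (p1=1, p2=0); site1: p1=p2=0.5 with n=4 copies
    dosage = np.array([[2, 2, 0, 0], [1, 1, 1, 1]], dtype=np.int8)
    geno = _geno(dosage, accessions=list(taxon_of))
    row = popgen.fst_gene(geno, samples, {"g": np.array([0, 1])}, "wild_vs_emmer").iloc[0]
    a0, b0 = popgen.fst_site(1.0, 4, 0.0, 4)
    a1, b1 = popgen.fst_site(0.5, 4, 0.5, 4)
    expected = (a0 + a1) / (b0 + b1)
    assert row["fst"] == pytest.approx(expected)
    mean_of_ratios = np.mean([a0 / b0, a1 / b1])
    assert row["fst"] != pytest.approx(mean_of_ratios)
    # the printed 2-site arithmetic example
    assert (1.0 - 0.05) / (1.0 + 0.5) == pytest.approx(0.6333, abs=5e-4)


def test_fst_gene_no_usable_sites():
    taxon_of = {"w1": "wild_emmer", "w2": "wild_emmer",
                "e1": "emmer", "e2": "emmer"}
    samples = _samples(taxon_of)
    geno = _geno(np.zeros((1, 4), dtype=np.int8), accessions=list(taxon_of))
    row = popgen.fst_gene(geno, samples, {"empty": np.array([], dtype=int)},
                          "wild_vs_emmer").iloc[0]
    assert row["n_sites"] == 0 and np.isnan(row["fst"])


def test_fst_null_within_monte_carlo_error():
    """With no population structure (F=0) the genome-wide estimate sits
    within 3 bootstrap SEs of zero."""
    cfg = SimConfig(n_genes=500, n_sites_per_gene=10, fst=(0.0, 0.0, 0.0), seed=31)
    geno = simulate_genotypes(cfg)
    samples = make_sample_table(cfg)
    est = popgen.fst_genome(geno, samples, "wild_vs_emmer")
    from qstscan.popgen import _fst_components, _pair_freqs

    a, b, ok = _fst_components(*_pair_freqs(geno, samples, "wild_vs_emmer"))
    rng = np.random.default_rng(0)
    n = ok.sum()
    boots = [
        a[ok][idx].sum() / b[ok][idx].sum()
        for idx in (rng.integers(0, n, n) for _ in range(200))
    ]
    assert abs(est) <= 3 * np.std(boots)


# ---------------------------------------------------------------------------
# thinning and PCA
# ---------------------------------------------------------------------------

def test_thin_snps_window_rule():
    dosage = np.zeros((3, 2), dtype=np.int8)
    geno = _geno(dosage, positions=[100, 400_000, 600_000])
    out = popgen.thin_snps(geno, window=500_000)
    assert list(out.sites["pos"]) == [100, 600_000]
    one = popgen.thin_snps(_geno(np.zeros((4, 2), dtype=np.int8),
                                 positions=[1, 2, 3, 4]), window=500_000)
    assert one.n_sites == 1


def test_pca_identical_accessions_coincide():
    dosage = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1], [0, 0, 2]], dtype=np.int8)
    coords = popgen.genotype_pca(_geno(dosage))
    np.testing.assert_allclose(
        coords.iloc[0].to_numpy(), coords.iloc[1].to_numpy(), atol=1e-10
    )


def test_pca_equidistant_triple_forms_equilateral_triangle():
    # three accessions pairwise differing at disjoint site pairs -> equal distances
    dosage = np.array(
        [[2, 0, 0], [2, 0, 0], [0, 2, 0], [0, 2, 0], [0, 0, 2], [0, 0, 2]],
        dtype=np.int8,
    )
    coords = popgen.genotype_pca(_geno(dosage)).to_numpy()
    d01 = np.linalg.norm(coords[0] - coords[1])
    d02 = np.linalg.norm(coords[0] - coords[2])
    d12 = np.linalg.norm(coords[1] - coords[2])
    assert d01 == pytest.approx(d02, rel=1e-9) == pytest.approx(d12, rel=1e-9)


def test_pca_zero_shared_sites_errors():
    dosage = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
    with pytest.raises(ValueError, match="share no genotyped sites"):
        popgen.genotype_pca(_geno(dosage))


def test_pca_recovers_simulated_taxa():
    """k-means on PC1-PC2 of an F=0.3 simulation recovers the three taxa
    (adjusted Rand > 0.9)."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    cfg = SimConfig(n_genes=100, n_sites_per_gene=10, fst=(0.3, 0.3, 0.3), seed=41)
    geno = simulate_genotypes(cfg)
    samples = make_sample_table(cfg)
    coords = popgen.genotype_pca(geno, n_components=2)
    labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(
        coords.to_numpy()
    )
    taxon_of = samples.drop_duplicates("genotype_id").set_index("genotype_id")["taxon"]
    truth = taxon_of.loc[coords.index].to_numpy()
    assert adjusted_rand_score(truth, labels) > 0.9
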