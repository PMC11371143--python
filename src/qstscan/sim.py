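"""Synthetic expression and genotype data with known ground truth.

Emulates the study design: three tetraploid wheat taxa (wild emmer, emmer,
durum) with 10/10/12 genotypes, two nitrogen levels, two replicates per
genotype and level. Expression counts are negative binomial around a latent
log-mean that follows the nested random-effects model

    Y = mu0 + S_i + G_j(i) + N_k + (SxN)_ik + (GxN)_jk(i) + eps_l(ijk)

with each effect drawn from a zero-mean normal with its configured variance.
Genotypes follow the Balding-Nichols model: per-taxon allele frequencies are
Beta-distributed around an ancestral frequency with divergence parameter F_t,
so the configured F is the analytic target of the downstream Fst estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import NITROGEN_LEVELS, TAXA, GenotypeMatrix

_GENO_PREFIX = {"wild_emmer": "we", "emmer": "em", "durum": "du"}


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    Variance components are on the natural-log expression scale and may be
    scalars (shared by all genes) or arrays of length n_genes. `phi` is the
    negative-binomial dispersion in the var = m + phi * m^2 parameterization;
    phi = 0 degenerates to Poisson. `fst` holds one Balding-Nichols divergence
    parameter per taxon, in TAXA order.
    """

    n_genes: int = 200
    n_genotypes: tuple[int, int, int] = (10, 10, 12)
    n_reps: int = 2
    mu0: float = float(np.log(200.0))
    v_s: float | np.ndarray = 0.1
    v_g: float | np.ndarray = 0.3
    v_n: float | np.ndarray = 0.05
    v_sxn: float | np.ndarray = 0.05
    v_gxn: float | np.ndarray = 0.05
    v_e: float | np.ndarray = 0.1
    phi: float = 0.1
    n_sites_per_gene: int = 10
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    fst: tuple[float, float, float] = (0.1, 0.1, 0.2)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu0):
            raise ValueError("mu0 must be finite")
        for name in ("v_s", "v_g", "v_n", "v_sxn", "v_gxn", "v_e"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"variance component {name} must be >= 0")
        if self.phi < 0:
            raise ValueError("NB dispersion phi must be >= 0")
        if any(n < 1 for n in self.n_genotypes) or self.n_reps < 1 or self.n_genes < 1:
            raise ValueError("counts must be >= 1")
        if any(not (0.0 <= f < 1.0) for f in self.fst):
            raise ValueError("Balding-Nichols F must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def component(self, name: str) -> np.ndarray:
        """Per-gene values of a variance component, broadcast to n_genes."""
        return np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (self.n_genes,))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def make_sample_table(config: SimConfig) -> pd.DataFrame:
    """The full factorial sample sheet: genotype x nitrogen x replicate."""
    rows = []
    for taxon, n_geno in zip(TAXA, config.n_genotypes):
        for j in range(1, n_geno + 1):
            geno = f"{_GENO_PREFIX[taxon]}{j:02d}"
            for nitrogen in NITROGEN_LEVELS:
                for rep in range(1, config.n_reps + 1):
                    rows.append(
                        (f"{geno}_{nitrogen}_{rep}", geno, taxon, nitrogen, rep)
                    )
    return pd.DataFrame(
        rows, columns=["sample_id", "genotype_id", "taxon", "nitrogen", "replicate"]
    )


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw counts from the random-effects model.

    Returns (counts, samples, truth): counts is a gene x sample integer
    DataFrame; truth records the variance components each gene was simulated
    with, plus the analytic broad-sense heritability and SxN fraction implied
    by them.
    """
    rng = _rng_children(config.seed, 2)[0]
    samples = make_sample_table(config)
    n_samples = len(samples)

    taxon_idx = pd.Categorical(samples["taxon"], categories=TAXA).codes
    geno_codes, _ = pd.factorize(samples["genotype_id"])
    n_idx = pd.Categorical(samples["nitrogen"], categories=NITROGEN_LEVELS).codes
    n_geno = geno_codes.max() + 1
    sxn_idx = taxon_idx * 2 + n_idx
    gxn_idx = geno_codes * 2 + n_idx

    v = {name: config.component(name) for name in ("v_s", "v_g", "v_n", "v_sxn", "v_gxn", "v_e")}

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    for g in range(config.n_genes):
        s_eff = rng.normal(0.0, np.sqrt(v["v_s"][g]), len(TAXA))
        g_eff = rng.normal(0.0, np.sqrt(v["v_g"][g]), n_geno)
        n_eff = rng.normal(0.0, np.sqrt(v["v_n"][g]), 2)
        sxn_eff = rng.normal(0.0, np.sqrt(v["v_sxn"][g]), len(TAXA) * 2)
        gxn_eff = rng.normal(0.0, np.sqrt(v["v_gxn"][g]), n_geno * 2)
        eps = rng.normal(0.0, np.sqrt(v["v_e"][g]), n_samples)
        eta = (
            config.mu0
            + s_eff[taxon_idx]
            + g_eff[geno_codes]
            + n_eff[n_idx]
            + sxn_eff[sxn_idx]
            + gxn_eff[gxn_idx]
            + eps
        )
        mean = np.exp(eta)
        if config.phi == 0.0:
            counts[g] = rng.poisson(mean)
        else:
            r = 1.0 / config.phi
            counts[g] = rng.negative_binomial(r, r / (r + mean))

    gene_ids = [f"gene{g + 1:05d}" for g in range(config.n_genes)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples["sample_id"].to_numpy())

    n_levels = 2
    va = (
        v["v_s"] + v["v_g"] + v["v_n"]
        + v["v_sxn"] / n_levels + v["v_gxn"] / n_levels + v["v_e"] / n_levels
    )
    total = v["v_s"] + v["v_g"] + v["v_n"] + v["v_sxn"] + v["v_gxn"] + v["v_e"]
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(va > 0, (v["v_s"] + v["v_g"]) / np.where(va > 0, va, 1.0), 0.0)
        sxn_frac = np.where(total > 0, v["v_sxn"] / np.where(total > 0, total, 1.0), 0.0)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            **{name: v[name] for name in v},
            "h2_true": h2,
            "sxn_frac_true": sxn_frac,
        }
    )
    return counts_df, samples, truth


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw a Balding-Nichols genotype matrix for the study accessions.

    Sites are laid out in one block per gene (see :func:`gene_models`) on a
    single synthetic chromosome. Per site: ancestral frequency p uniform on
    the configured range; per-taxon frequency Beta(p(1-F)/F, (1-p)(1-F)/F)
    (p itself when F = 0); accession dosage Binomial(2, p_t).
    """
    rng = _rng_children(config.seed, 2)[1]
    samples = make_sample_table(config)
    accessions = samples["genotype_id"].drop_duplicates().tolist()
    taxon_of = samples.drop_duplicates("genotype_id").set_index("genotype_id")["taxon"]
    n_sites = config.n_genes * config.n_sites_per_gene

    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, n_sites)

    dosage = np.empty((n_sites, len(accessions)), dtype=np.int8)
    for t, taxon in enumerate(TAXA):
        f = config.fst[t]
        if f == 0.0:
            p_t = p_anc
        else:
            scale = (1.0 - f) / f
            p_t = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
        cols = np.flatnonzero((taxon_of.loc[accessions] == taxon).to_numpy())
        dosage[:, cols] = rng.binomial(2, p_t[:, None], (n_sites, len(cols)))

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1

    genes = gene_models(config)
    pos = np.concatenate(
        [
            g.start + 1 + np.arange(config.n_sites_per_gene) * (
                (g.end - g.start) // config.n_sites_per_gene
            )
            for g in genes.itertuples(index=False)
        ]
    )
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(sites=sites, accessions=accessions, dosage=dosage)


def gene_models(config: SimConfig) -> pd.DataFrame:
    """Gene intervals matching :func:`simulate_genotypes` site layout.

    Gene g occupies [g*10000, g*10000 + 2000) on chr1 (0-based half-open).
    """
    starts = np.arange(config.n_genes) * 10_000
    return pd.DataFrame(
        {
            "gene_id": [f"gene{g + 1:05d}" for g in range(config.n_genes)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + 2_000,
            "strand": "+",
        }
    )
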