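import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from qstscan import prep, quantgen
from qstscan.quantgen import (
    full_model_kernels,
    heritability,
    moment_estimates,
    reml_fit,
    sxn_fraction,
)
from qstscan.sim import SimConfig, simulate_expression


def test_heritability_arithmetic():
    comps = {"v_s": 2, "v_g": 2, "v_n": 1, "v_sxn": 1, "v_gxn": 1, "v_e": 2}
    # V_A = 2+2+1+0.5+0.5+1 = 7
    assert heritability(comps) == pytest.approx(4 / 7)
    only_g = {k: 0 for k in comps} | {"v_g": 3}
    assert heritability(only_g) == 1.0
    only_e = {k: 0 for k in comps} | {"v_e": 3}
    assert heritability(only_e) == 0.0
    assert heritability({k: 0 for k in comps}) == 0.0


def test_sxn_fraction_normalization():
    comps = {"v_s": 1, "v_g": 1, "v_n": 1, "v_sxn": 1, "v_gxn": 0.5, "v_e": 0.5}
    assert sxn_fraction(comps | {"v_sxn": 1.0}) == pytest.approx(1 / 5)
    assert sxn_fraction(comps | {"v_sxn": 0.0}) == 0.0
    rng = np.random.default_rng(0)
    for _ in range(10):
        c = dict(zip(comps, rng.uniform(0, 2, 6)))
        fracs = [c[k] / sum(c.values()) for k in c]
        assert sum(fracs) == pytest.approx(1.0)
        assert sxn_fraction(c) == pytest.approx(c["v_sxn"] / sum(c.values()))


def test_constant_response_gives_zero_components(design_samples):
    norm = pd.DataFrame(
        [[3.0] * len(design_samples)],
        index=pd.Index(["g"], name="gene_id"),
        columns=design_samples["sample_id"],
    )
    res = quantgen.fit_full_model(norm, design_samples, "g")
    assert all(v == 0.0 for v in res.components().values())
    assert res.h2 == 0.0
    assert res.fit_status != "failed"


def test_incomplete_design_fails_gracefully(design_samples):
    sub = design_samples[design_samples["taxon"] != "durum"]
    norm = pd.DataFrame(
        [np.arange(len(sub), dtype=float)],
        index=pd.Index(["g"], name="gene_id"),
        columns=sub["sample_id"],
    )
    res = quantgen.fit_full_model(norm, sub, "g")
    assert res.fit_status == "failed"


def test_pure_noise_simulation_recovers_null_taxon_variance():
    """With only residual variance, taxon and genotype components stay small."""
    cfg = SimConfig(
        n_genes=200, v_s=0, v_g=0, v_n=0, v_sxn=0, v_gxn=0, v_e=1.0,
        phi=0.0, mu0=float(np.log(500.0)), seed=6,
    )
    counts, samples, _ = simulate_expression(cfg)
    vc = quantgen.fit_variance_components(prep.normalize(counts), samples)
    assert vc["v_s"].median() < 0.1
    assert vc["v_g"].median() < 0.1


def test_h2_and_bounds_on_recovery_sim(h2_recovery_fit):
    _, _, _, truth, vc = h2_recovery_fit
    assert ((vc["h2"] >= 0) & (vc["h2"] <= 1)).all()
    assert ((vc["sxn_frac"] >= 0) & (vc["sxn_frac"] <= 1)).all()
    assert (vc[["v_s", "v_g", "v_n", "v_sxn", "v_gxn", "v_e"]] >= 0).all().all()


def test_component_recovery_for_replicated_factors():
    """Median relative bias < 15% for the components estimated with many
    levels (genotype, genotype x nitrogen, residual). Components carried by
    only 2-3 levels (taxon, nitrogen, taxon x nitrogen) have chi-square
    median attenuation that no estimator can remove and are excluded."""
    cfg = SimConfig(
        n_genes=200, v_s=0.5, v_g=0.5, v_n=0.5, v_sxn=0.5, v_gxn=0.5, v_e=0.5,
        phi=0.05, mu0=float(np.log(500.0)), seed=11,
    )
    counts, samples, _ = simulate_expression(cfg)
    vc = quantgen.fit_variance_components(prep.normalize(counts), samples)
    ln2sq = np.log(2.0) ** 2  # estimates are on the log2 scale
    for comp in ("v_g", "v_gxn", "v_e"):
        est = vc[comp].median() * ln2sq
        assert abs(est - 0.5) / 0.5 < 0.15, comp


def test_moments_and_reml_agree_on_replicated_components():
    """On the balanced complete design the method-of-moments fallback and
    REML agree (medians within 0.05) for the well-identified components."""
    cfg = SimConfig(
        n_genes=100, v_s=0.5, v_g=1.0, v_n=0.1, v_sxn=0.1, v_gxn=0.5, v_e=0.5,
        phi=0.05, seed=11,
    )
    counts, samples, _ = simulate_expression(cfg)
    norm = prep.normalize(counts)
    kernels = full_model_kernels(samples)
    mom = np.array([moment_estimates(norm.iloc[g].to_numpy(), kernels) for g in range(100)])
    reml = np.array([reml_fit(norm.iloc[g].to_numpy(), kernels)[0] for g in range(100)])
    med_diff = np.abs(np.median(mom, axis=0) - np.median(reml, axis=0))
    for j, comp in enumerate(("v_s", "v_g", "v_n", "v_sxn", "v_gxn", "v_e")):
        if comp in ("v_g", "v_gxn", "v_e"):
            assert med_diff[j] < 0.05, comp


def test_reml_matches_lme4_oracle(h2_recovery_fit):
    """The six-component REML fit agrees with lme4's lmer on one gene."""
    _, norm, samples, _, vc = h2_recovery_fit
    gene = norm.index[0]
    df = samples.copy()
    df["y"] = norm.loc[gene, df["sample_id"].to_numpy()].to_numpy()
    csv = df.to_csv(index=False)
    script = textwrap.dedent(
        """
        suppressMessages(library(lme4))
        d <- read.csv("stdin")
        fit <- lmer(y ~ 1 + (1|taxon) + (1|genotype_id) + (1|nitrogen)
                    + (1|taxon:nitrogen) + (1|genotype_id:nitrogen), data = d,
                    control = lmerControl(check.conv.singular = "ignore"))
        vc <- as.data.frame(VarCorr(fit))
        vc$grp <- sub(":", "_", vc$grp)
        write.csv(vc[, c("grp", "vcov")], row.names = FALSE)
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], input=csv, capture_output=True, text=True, check=True
    )
    ref = pd.read_csv(pd.io.common.StringIO(out.stdout)).set_index("grp")["vcov"]
    ours = vc.set_index("gene_id").loc[gene]
    mapping = {
        "taxon": "v_s",
        "genotype_id": "v_g",
        "nitrogen": "v_n",
        "taxon_nitrogen": "v_sxn",
        "genotype_id_nitrogen": "v_gxn",
        "Residual": "v_e",
    }
    for grp, comp in mapping.items():
        assert ours[comp] == pytest.approx(ref[grp], abs=0.02), comp


def test_qst_closed_form_and_null(design_samples):
    """Q_ST is V_S/(V_S+V_G): equal estimated components give 0.5, and a
    no-taxon-effect simulation puts the median near zero."""
    cfg = SimConfig(
        n_genes=40, v_s=0.0, v_g=1.0, v_n=0, v_sxn=0, v_gxn=0, v_e=0.25,
        phi=0.0, mu0=float(np.log(500.0)), seed=13,
    )
    counts, samples, _ = simulate_expression(cfg)
    norm = prep.normalize(counts)
    qst = quantgen.qst_table(norm, samples)
    assert qst["qst"].median() < 0.1
    defined = qst["qst"].dropna()
    assert ((defined >= 0) & (defined <= 1)).all()


def test_qst_shrinks_under_taxon_label_permutation():
    """Permuting taxon labels destroys the taxon effect: the permuted median
    Q_ST drops below the unpermuted one."""
    cfg = SimConfig(
        n_genes=40, v_s=2.0, v_g=0.5, v_n=0, v_sxn=0, v_gxn=0, v_e=0.25,
        phi=0.0, seed=17,
    )
    counts, samples, _ = simulate_expression(cfg)
    norm = prep.normalize(counts)
    q_obs = quantgen.qst_table(norm, samples)["qst"].median()
    rng = np.random.default_rng(0)
    geno = samples.drop_duplicates("genotype_id")[["genotype_id", "taxon"]]
    shuffled = geno.assign(taxon=rng.permutation(geno["taxon"].to_numpy()))
    perm = samples.drop(columns="taxon").merge(shuffled, on="genotype_id")
    q_perm = quantgen.qst_table(norm, perm)["qst"].median()
    assert q_perm < q_obs


def test_qst_undefined_for_single_genotype_taxon(design_samples):
    sub = design_samples[
        (design_samples["taxon"] == "emmer")
        | (design_samples["genotype_id"] == "du01")
    ]
    norm = pd.DataFrame(
        [np.arange(len(sub), dtype=float)],
        index=pd.Index(["g"], name="gene_id"),
        columns=sub["sample_id"],
    )
    q = quantgen.fit_qst(norm, sub, "g", "emmer_vs_durum", "low")
    assert np.isnan(q)
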