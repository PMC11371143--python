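"""End-to-end orchestration from a single YAML/dict config.

Stage order: (simulate?) -> prep -> evolvability -> variance components ->
Q_ST -> popgen -> scan -> differential expression -> integrate. Every stage
reads files written by the previous one, so the pipeline is re-entrant from
any intermediate TSV; a manifest JSON records the config, its hash, and the
row counts at each filter step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import de as de_mod
from . import evolvability as evol
from . import io, popgen, prep, quantgen, scan as scan_mod, sim
from .datatypes import NITROGEN_LEVELS, PAIRS, TAXA

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "simulate": True,
    "sim": {},  # SimConfig overrides
    "inputs": {},  # counts, samples, vcf, genes when simulate is false
    "min_cpm": 1.0,
    "min_samples": 10,
    "transform": "log2cpm1",
    "max_missing": 0.5,
    "min_maf": 0.01,
    "thin_window": 500_000,
    "total_sites": None,  # default: n_genes x 2000 surveyed bases (simulation layout)
    "h2_min": 0.7,
    "sxn_min": 0.2,
    "tail_q": 0.95,
    "fst_min": 0.01,
    "prefilter_logic": "or",
    "padj_alpha": 0.001,
    "seed": 0,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_all(config: dict | None = None, outdir: str | Path = "qstscan_out") -> Path:
    """Run every stage; returns the output directory.

    Any stage failure is re-raised with the stage name prepended.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest: dict = {"config": {k: v for k, v in cfg.items()}, "config_hash": chash, "stages": {}}

    stage = "setup"
    try:
        if cfg["simulate"]:
            stage = "simulate"
            sim_cfg = sim.SimConfig(seed=cfg["seed"], **cfg["sim"])
            counts, samples, truth = sim.simulate_expression(sim_cfg)
            geno = sim.simulate_genotypes(sim_cfg)
            genes = sim.gene_models(sim_cfg)
            io.write_counts(counts, outdir / "counts.tsv")
            io.write_samples(samples, outdir / "samples.tsv")
            io.write_vcf(geno, outdir / "sites.vcf")
            io.write_bed(genes, outdir / "genes.bed")
            io.write_table(truth, outdir / "truth.tsv")
            if cfg["total_sites"] is None:
                cfg["total_sites"] = sim_cfg.n_genes * 2000
        else:
            stage = "load"
            counts = io.read_counts(cfg["inputs"]["counts"])
            samples = io.read_samples(cfg["inputs"]["samples"])
            geno = io.read_vcf(cfg["inputs"]["vcf"])
            genes = io.read_gene_models(cfg["inputs"]["genes"])
            if cfg["total_sites"] is None:
                raise ValueError("total_sites is required for per-site diversity")
        manifest["stages"]["input"] = {
            "n_genes": len(counts),
            "n_samples": counts.shape[1],
            "n_sites": geno.n_sites,
        }

        stage = "prep"
        kept = prep.filter_genes(counts, samples, cfg["min_cpm"], cfg["min_samples"])
        counts_f = counts.loc[kept.union]
        norm = prep.normalize(counts_f, cfg["transform"])
        io.write_matrix(norm, outdir / "norm.tsv")
        manifest["stages"]["prep"] = {"n_genes_retained": len(kept.union)}

        stage = "evolvability"
        cva = evol.cva_table(norm, samples)
        io.write_table(cva, outdir / "cva.tsv")
        summary = evol.cva_summary(cva)
        summary["means"].to_csv(outdir / "cva_means.tsv", sep="\t")
        io.write_table(summary["losses"], outdir / "cva_losses.tsv")

        stage = "varcomp"
        varcomp = quantgen.fit_variance_components(norm, samples)
        io.write_table(varcomp, outdir / "varcomp.tsv")

        stage = "qst"
        qst = quantgen.qst_table(norm, samples)
        io.write_table(qst, outdir / "qst.tsv")

        stage = "popgen"
        geno_f = popgen.filter_snps(geno, cfg["max_missing"], cfg["min_maf"])
        manifest["stages"]["popgen"] = {
            "n_sites_after_filter": geno_f.n_sites,
        }
        gene_sites = io.assign_sites_to_genes(geno_f, genes)
        fst = popgen.fst_table(geno_f, samples, gene_sites)
        io.write_table(fst, outdir / "fst.tsv")
        div = pd.DataFrame(
            [
                popgen.diversity_stats(geno_f, samples, t, cfg["total_sites"]).__dict__
                for t in TAXA
            ]
        )
        io.write_table(div, outdir / "diversity.tsv")
        thinned = popgen.thin_snps(geno_f, cfg["thin_window"])
        manifest["stages"]["popgen"]["n_sites_after_thin"] = thinned.n_sites
        pca = popgen.genotype_pca(thinned)
        pca.to_csv(outdir / "pca.tsv", sep="\t")

        stage = "scan"
        result = scan_mod.run_scan(
            varcomp,
            qst,
            fst,
            h2_min=cfg["h2_min"],
            sxn_min=cfg["sxn_min"],
            tail_q=cfg["tail_q"],
            fst_min=cfg["fst_min"],
            prefilter_logic=cfg["prefilter_logic"],
        )
        io.write_table(result["scan"], outdir / "scan.tsv")
        io.write_table(result["membership"], outdir / "scan_membership.tsv")
        manifest["stages"]["scan"] = {
            "n_prefiltered": len(result["prefiltered"]),
            "n_comparisons": result["n_comparisons"],
            "n_intersection": len(result["intersection"]),
        }

        stage = "de"
        deg_lists = {}
        for taxon in TAXA:
            degs = de_mod.de_test(norm, samples, taxon, alpha=cfg["padj_alpha"])
            io.write_table(degs, outdir / f"degs_{taxon}.tsv")
            deg_lists[taxon] = degs
        manifest["stages"]["de"] = {
            t: int(d["is_deg"].sum()) for t, d in deg_lists.items()
        }

        stage = "integrate"
        integ = de_mod.integrate(result, deg_lists, gene_models=genes)
        io.write_table(integ["table"], outdir / "integrated.tsv")
        manifest["stages"]["integrate"] = integ["summary"]
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete (config %s) -> %s", chash, outdir)
    return outdir
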