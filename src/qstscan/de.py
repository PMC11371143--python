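"""Differential expression between nitrogen conditions, Venn partitioning,
expression PCA, and integration with the selection scan.

The built-in test is a per-gene Welch two-sample comparison of normalized
(log2-scale) expression with Benjamini-Hochberg adjustment; it deliberately
stands in for heavier count-model pipelines, and `intersect_deg_lists`
accepts externally produced DEG tables so the multi-method intersection
protocol can be replicated with any callers the user prefers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import NITROGEN_LEVELS, PAIRS, validate_deg_list


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sided p with explicit degenerate handling: both groups
    constant -> p=1 if means equal else p=0."""
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def de_test(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    taxon: str,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """High-N vs low-N DEGs within one taxon.

    log2FC = mean(high) - mean(low) on the log2 expression scale; BH-adjusted
    Welch p-values; a gene is a DEG iff padj < alpha.
    """
    sub = samples[samples["taxon"] == taxon]
    hi = [s for s in sub.loc[sub["nitrogen"] == "high", "sample_id"] if s in norm.columns]
    lo = [s for s in sub.loc[sub["nitrogen"] == "low", "sample_id"] if s in norm.columns]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError(f"taxon {taxon!r} needs >= 2 samples per nitrogen level")
    a = norm[hi].to_numpy(dtype=float)
    b = norm[lo].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.array([_welch(a[i], b[i]) for i in range(len(norm))])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": norm.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
            "is_deg": padj < alpha,
        }
    )


def de_test_between_taxa(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    pair: str,
    nitrogen: str,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """DEGs between the taxa of a pair at one nitrogen level.

    Replicates are first averaged per genotype so genotypes are the
    independent units; then a Welch comparison between the two taxa.
    """
    t1, t2 = PAIRS[pair]
    sub = samples[(samples["taxon"].isin((t1, t2))) & (samples["nitrogen"] == nitrogen)]
    cols = [s for s in sub["sample_id"] if s in norm.columns]
    geno = sub.set_index("sample_id").loc[cols, "genotype_id"]
    gm = norm[cols].T.groupby(geno.to_numpy()).mean().T
    taxon_of = sub.drop_duplicates("genotype_id").set_index("genotype_id")["taxon"]
    g1 = [g for g in gm.columns if taxon_of[g] == t1]
    g2 = [g for g in gm.columns if taxon_of[g] == t2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(f"pair {pair!r} needs >= 2 genotypes per taxon")
    a = gm[g1].to_numpy(dtype=float)
    b = gm[g2].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.array([_welch(a[i], b[i]) for i in range(len(gm))])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": gm.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
            "is_deg": padj < alpha,
        }
    )


def intersect_deg_lists(lists: list[pd.DataFrame]) -> pd.DataFrame:
    """Genes called in every provided DEG list with agreeing direction.

    Genes whose direction conflicts across lists are dropped with a warning.
    The first list's log2fc/padj are carried through.
    """
    if not lists:
        raise ValueError("need at least one DEG list")
    lists = [
        validate_deg_list(df[df["is_deg"]] if "is_deg" in df.columns else df)
        for df in lists
    ]
    common = set(lists[0]["gene_id"])
    for df in lists[1:]:
        common &= set(df["gene_id"])
    directions = {}
    conflicted = set()
    for df in lists:
        for g, d in zip(df["gene_id"], df["direction"]):
            if g not in common:
                continue
            if g in directions and directions[g] != d:
                conflicted.add(g)
            directions[g] = d
    if conflicted:
        warnings.warn(
            f"dropping {len(conflicted)} gene(s) with conflicting direction"
        )
        common -= conflicted
    first = lists[0]
    return first[first["gene_id"].isin(common)].reset_index(drop=True)


def venn_partition(deg_sets: dict[str, set]) -> pd.DataFrame:
    """The 7 disjoint cells of a 3-set Venn partition.

    One row per non-empty membership pattern, with the gene count, the gene
    ids, and for each set the percentage of that set's genes in the cell.
    """
    names = list(deg_sets)
    if len(names) != 3:
        raise ValueError("venn_partition expects exactly 3 sets")
    union = set().union(*deg_sets.values())
    rows = []
    for mask in range(1, 8):
        members = [names[i] for i in range(3) if mask >> i & 1]
        cell = set(union)
        for i, name in enumerate(names):
            cell &= deg_sets[name] if mask >> i & 1 else union - deg_sets[name]
        row = {
            "cell": "+".join(members),
            "n": len(cell),
            "genes": ";".join(str(g) for g in sorted(cell, key=str)),
        }
        for name in names:
            total = len(deg_sets[name])
            row[f"pct_{name}"] = (
                100.0 * len(cell) / total if name in members and total else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def expression_pca(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    genes,
    nitrogen: str,
    n_components: int = 5,
) -> pd.DataFrame:
    """PCA of genotype-averaged expression at one nitrogen level.

    Genes are variables (centered, not scaled), genotypes are observations;
    deterministic up to axis sign. Returns coordinates with the explained
    variance ratio in .attrs["explained_variance_ratio"].
    """
    from sklearn.decomposition import PCA

    genes = pd.Index(genes)
    if len(genes) < 2:
        raise ValueError("expression PCA needs >= 2 genes")
    sub = samples[samples["nitrogen"] == nitrogen]
    cols = [s for s in sub["sample_id"] if s in norm.columns]
    geno = sub.set_index("sample_id").loc[cols, "genotype_id"]
    gm = norm.loc[genes, cols].T.groupby(geno.to_numpy()).mean()  # genotype x gene
    k = min(n_components, min(gm.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(gm.to_numpy())
    out = pd.DataFrame(
        coords,
        index=pd.Index(gm.index, name="genotype_id"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


def integrate(
    scan_result: dict,
    deg_lists: dict[str, pd.DataFrame],
    between_taxa_degs: pd.DataFrame | None = None,
    gene_models: pd.DataFrame | None = None,
) -> dict:
    """Join DEG calls with the selection scan.

    Returns a per-gene annotated table (DEG-in-any-taxon flag, per-taxon
    direction, number of comparisons flagged, intersection membership) plus
    overlap summary counts, and optionally a DEG count per chromosome.
    """
    deg_any: dict[str, dict] = {}
    for taxon, df in deg_lists.items():
        hits = df[df["is_deg"]] if "is_deg" in df.columns else df
        for g, d in zip(hits["gene_id"], hits["direction"]):
            deg_any.setdefault(g, {})[taxon] = d

    membership = scan_result["membership"].set_index("gene_id")
    intersection = scan_result["intersection"]
    all_genes = sorted(set(deg_any) | set(membership.index))
    rows = []
    for g in all_genes:
        n_flagged = int(membership["n_flagged"].get(g, 0))
        rows.append(
            {
                "gene_id": g,
                "deg_any_taxon": g in deg_any,
                **{
                    f"direction_{t}": deg_any.get(g, {}).get(t, "")
                    for t in deg_lists
                },
                "n_comparisons_flagged": n_flagged,
                "in_intersection": g in intersection,
            }
        )
    table = pd.DataFrame(rows)
    selected = set(membership.index[membership["n_flagged"] > 0])
    summary = {
        "n_deg_any": len(deg_any),
        "n_selected": len(selected),
        "n_deg_and_selected": len(set(deg_any) & selected),
        "n_intersection": len(intersection),
    }
    out = {"table": table, "summary": summary}
    if gene_models is not None:
        chrom_of = gene_models.set_index("gene_id")["chrom"]
        degs = [g for g in deg_any if g in chrom_of.index]
        out["deg_per_chromosome"] = (
            chrom_of.loc[degs].value_counts().rename_axis("chrom").rename("n_degs")
        )
    return out
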