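"""The Q_ST-F_ST selection scan.

Genes are first filtered on broad-sense heritability (H2 >= 0.7) with a
rescue rule for strong taxon x nitrogen interaction (SxN variance share >=
0.2, OR-combined by default so nitrogen-responsive genes are not lost). For
each of the six (taxon pair, nitrogen) comparisons, genes in the 5% right
tail of that comparison's Q_ST distribution (over the prefiltered genes) are
candidates; after dropping per-gene Fst values below 0.01, a candidate is
flagged as under putative directional selection iff Q_ST > F_ST. Q_ST < F_ST
marks stabilizing selection and equality is consistent with drift. The genes
flagged in all six comparisons form the headline intersection set.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import COMPARISONS

log = logging.getLogger(__name__)


def prefilter(
    varcomp: pd.DataFrame,
    h2_min: float = 0.7,
    sxn_min: float = 0.2,
    logic: str = "or",
) -> pd.Index:
    """Genes passing the heritability / interaction filter.

    logic="or" (default): H2 >= h2_min OR sxn_frac >= sxn_min (rescue
    semantics); logic="and" requires both. Failed fits never pass.
    """
    if logic not in ("or", "and"):
        raise ValueError("prefilter logic must be 'or' or 'and'")
    ok_fit = varcomp["fit_status"] != "failed"
    pass_h2 = (varcomp["h2"] >= h2_min) & ok_fit
    pass_sxn = (varcomp["sxn_frac"] >= sxn_min) & ok_fit
    keep = (pass_h2 | pass_sxn) if logic == "or" else (pass_h2 & pass_sxn)
    return pd.Index(varcomp.loc[keep, "gene_id"])


def qst_tail(
    qst: pd.DataFrame,
    genes: pd.Index,
    q: float = 0.95,
    min_n: int = 20,
) -> dict[tuple[str, str], set]:
    """Right-tail Q_ST genes per comparison.

    The threshold is the linear-interpolation q-quantile of the comparison's
    defined Q_ST values over the prefiltered genes; genes at or above it are
    retained (ties inclusive). Comparisons with fewer than min_n defined
    values are skipped with a warning.
    """
    sub = qst[qst["gene_id"].isin(set(genes))]
    out: dict[tuple[str, str], set] = {}
    for (pair, nitrogen), grp in sub.groupby(["pair", "nitrogen"], sort=False):
        vals = grp["qst"].dropna()
        if len(vals) < min_n:
            warnings.warn(
                f"comparison ({pair}, {nitrogen}): only {len(vals)} defined "
                f"Q_ST values (< {min_n}); skipped"
            )
            continue
        thresh = np.quantile(vals.to_numpy(), q)
        out[(pair, nitrogen)] = set(grp.loc[grp["qst"] >= thresh, "gene_id"])
    return out


def qst_fst_compare(
    tail: dict[tuple[str, str], set],
    qst: pd.DataFrame,
    fst: pd.DataFrame,
    varcomp: pd.DataFrame,
    h2_min: float = 0.7,
    sxn_min: float = 0.2,
    fst_min: float = 0.01,
) -> pd.DataFrame:
    """Per-gene, per-comparison scan table.

    One row per (gene, pair, nitrogen) with the filter flags and the
    selection label: "directional" iff Q_ST > F_ST (strict), "stabilizing"
    iff Q_ST < F_ST, "drift" at equality. Genes whose Fst is undefined or
    below fst_min get fst_ok=False and cannot be flagged.
    """
    vc = varcomp.set_index("gene_id")
    fst_of = fst.set_index(["gene_id", "pair"])["fst"]
    rows = []
    for row in qst.itertuples(index=False):
        key = (row.pair, row.nitrogen)
        in_tail = key in tail and row.gene_id in tail[key]
        f = fst_of.get((row.gene_id, row.pair), np.nan)
        fst_ok = bool(np.isfinite(f) and f >= fst_min)
        if row.gene_id in vc.index:
            passed_h2 = bool(vc.loc[row.gene_id, "h2"] >= h2_min)
            passed_sxn = bool(vc.loc[row.gene_id, "sxn_frac"] >= sxn_min)
        else:
            passed_h2 = passed_sxn = False
        directional = bool(
            in_tail and fst_ok and np.isfinite(row.qst) and row.qst > f
        )
        if not fst_ok or not np.isfinite(row.qst):
            label = "unclassified"
        elif row.qst > f:
            label = "directional"
        elif row.qst < f:
            label = "stabilizing"
        else:
            label = "drift"
        rows.append(
            (
                row.gene_id,
                row.pair,
                row.nitrogen,
                row.qst,
                f,
                passed_h2,
                passed_sxn,
                in_tail,
                fst_ok,
                directional,
                label,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "pair",
            "nitrogen",
            "qst",
            "fst",
            "passed_h2",
            "passed_sxn",
            "in_qst_tail",
            "fst_ok",
            "directional",
            "label",
        ],
    )


def intersect_comparisons(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-gene count and list of comparisons in which it was flagged.

    The genes with n_flagged equal to the number of computed comparisons
    (6 in the full design) are the headline intersection set.
    """
    flagged = scan[scan["directional"]]
    if flagged.empty:
        return pd.DataFrame(columns=["gene_id", "n_flagged", "comparisons"])
    labels = flagged["pair"] + ":" + flagged["nitrogen"]
    per_gene = (
        flagged.assign(label=labels)
        .groupby("gene_id")["label"]
        .agg(lambda v: ";".join(sorted(v)))
    )
    return pd.DataFrame(
        {
            "gene_id": per_gene.index,
            "n_flagged": [len(v.split(";")) for v in per_gene],
            "comparisons": per_gene.to_numpy(),
        }
    ).reset_index(drop=True)


def run_scan(
    varcomp: pd.DataFrame,
    qst: pd.DataFrame,
    fst: pd.DataFrame,
    h2_min: float = 0.7,
    sxn_min: float = 0.2,
    tail_q: float = 0.95,
    fst_min: float = 0.01,
    prefilter_logic: str = "or",
    tail_min_n: int = 20,
) -> dict:
    """Full scan: prefilter -> tail -> Q_ST/F_ST comparison -> intersection."""
    kept = prefilter(varcomp, h2_min, sxn_min, prefilter_logic)
    log.info("prefilter: %d of %d genes retained", len(kept), len(varcomp))
    tail = qst_tail(qst, kept, tail_q, tail_min_n)
    scan = qst_fst_compare(tail, qst, fst, varcomp, h2_min, sxn_min, fst_min)
    inter = intersect_comparisons(scan)
    n_comp = len(tail)
    headline = set(inter.loc[inter["n_flagged"] == n_comp, "gene_id"]) if n_comp else set()
    return {
        "prefiltered": kept,
        "tail": tail,
        "scan": scan,
        "membership": inter,
        "intersection": headline,
        "n_comparisons": n_comp,
    }
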