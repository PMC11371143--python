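"""Evolvability (additive coefficient of variation) and loss-of-diversity statistics.

CV_A for a gene within one taxon x nitrogen group is the sample standard
deviation of genotype-mean expression divided by the mean of those genotype
means; with inbred lines the between-line variance approximates the additive
variance, making this a standardized evolvability measure. The loss statistic
1 - x_derived/x_ancestral (flipped to x_ancestral/x_derived - 1 when diversity
increased) quantifies diversity lost across a domestication transition and is
applied identically to pi, theta and CV_A; two stage losses compose
multiplicatively.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NITROGEN_LEVELS, PAIRS, TAXA


def genotype_means(
    norm: pd.DataFrame, samples: pd.DataFrame, taxon: str, nitrogen: str
) -> pd.DataFrame:
    """Gene x genotype matrix of replicate-averaged expression for one group."""
    grp = samples[(samples["taxon"] == taxon) & (samples["nitrogen"] == nitrogen)]
    cols = [s for s in grp["sample_id"] if s in norm.columns]
    if not cols:
        raise ValueError(f"no samples for taxon={taxon!r}, nitrogen={nitrogen!r}")
    sub = norm[cols]
    geno = grp.set_index("sample_id").loc[cols, "genotype_id"]
    return sub.T.groupby(geno.to_numpy()).mean().T


def cva_gene(
    norm: pd.DataFrame, samples: pd.DataFrame, gene: str, taxon: str, nitrogen: str
) -> float:
    """CV_A of one gene in one taxon x nitrogen group.

    Returns NaN (undefined) when the mean of genotype means is zero; raises
    when fewer than two genotypes are available.
    """
    m = genotype_means(norm, samples, taxon, nitrogen).loc[gene].to_numpy(dtype=float)
    if len(m) < 2:
        raise ValueError("CV_A needs >= 2 genotypes")
    mean = m.mean()
    if mean == 0.0:
        return float("nan")
    return float(m.std(ddof=1) / mean)


def cva_table(norm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-gene CV_A over all 6 taxon x nitrogen groups (NaN = undefined)."""
    frames = []
    for taxon in TAXA:
        for nitrogen in NITROGEN_LEVELS:
            m = genotype_means(norm, samples, taxon, nitrogen)
            if m.shape[1] < 2:
                raise ValueError(f"group ({taxon}, {nitrogen}) has < 2 genotypes")
            means = m.mean(axis=1)
            sds = m.std(axis=1, ddof=1)
            cva = np.where(means.to_numpy() != 0.0, sds / means.replace(0.0, np.nan), np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": m.index,
                        "taxon": taxon,
                        "nitrogen": nitrogen,
                        "cva": cva,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def loss_of_diversity(x_ancestral: float, x_derived: float) -> float:
    """Fractional diversity loss across a transition (negative = gain).

    1 - x_derived/x_ancestral when diversity decreased; x_ancestral/x_derived - 1
    (a negative number) when it increased. Both inputs must be positive.
    """
    if x_ancestral <= 0 or x_derived <= 0:
        raise ValueError("diversity values must be positive")
    if x_derived <= x_ancestral:
        return 1.0 - x_derived / x_ancestral
    return x_ancestral / x_derived - 1.0


def compose_losses(l_pd: float, l_sd: float) -> float:
    """Cumulative loss over two stages: 1 - (1 - l_pd)(1 - l_sd).

    Exact whenever both stage losses come from a monotonically decreasing
    sequence (no flip branch).
    """
    if l_pd >= 1 or l_sd >= 1:
        raise ValueError("stage losses must be < 1")
    return 1.0 - (1.0 - l_pd) * (1.0 - l_sd)


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(x, y, exact_max: int = 12) -> tuple[float, float]:
    """Mann-Whitney U (for x) with a two-sided p-value.

    Uses exhaustive enumeration of all C(n+m, n) labelings when n + m <=
    exact_max (valid under ties), otherwise the normal approximation with
    midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    center = n * m / 2.0

    if n + m <= exact_max:
        dev = abs(u_x - center)
        count = total = 0
        rank_sum_base = n * (n + 1) / 2.0
        for idx in itertools.combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - rank_sum_base
            total += 1
            if abs(u - center) >= dev - 1e-12:
                count += 1
        return u_x, count / total

    # normal approximation, midrank tie correction
    nm = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (nm * (nm - 1))
    var = n * m / 12.0 * (nm + 1 - tie_term)
    if var == 0:
        return u_x, 1.0
    z = (abs(u_x - center) - 0.5) / math.sqrt(var)
    return u_x, float(2.0 * stats.norm.sf(max(z, 0.0)))


def cva_summary(cva: pd.DataFrame, genes: pd.Index | list | None = None) -> dict:
    """Group means, per-transition losses, and Mann-Whitney comparisons.

    Returns a dict with:
      means     -- DataFrame taxon x nitrogen of mean CV_A over genes with a
                   defined value (optionally restricted to `genes`)
      losses    -- DataFrame per (transition, nitrogen): loss on the group means
      mw_pvalues-- dict of two-sided Mann-Whitney p-values on per-gene loss
                   distributions: lpd vs lsd within each nitrogen level, and
                   high vs low N within each transition
    """
    df = cva if genes is None else cva[cva["gene_id"].isin(set(genes))]
    if df.empty:
        raise ValueError("no CV_A rows selected")
    means = (
        df.dropna(subset=["cva"])
        .groupby(["taxon", "nitrogen"])["cva"]
        .mean()
        .unstack("nitrogen")
    )
    if means.isna().any().any() or len(means) < len(TAXA):
        raise ValueError("a taxon x nitrogen group has no defined CV_A values")

    transitions = {"lpd": ("wild_emmer", "emmer"), "lsd": ("emmer", "durum")}
    rows = []
    per_gene_losses: dict[tuple[str, str], np.ndarray] = {}
    wide = df.pivot_table(index="gene_id", columns=["taxon", "nitrogen"], values="cva")
    for nitrogen in NITROGEN_LEVELS:
        for name, (anc, der) in transitions.items():
            loss = loss_of_diversity(means.loc[anc, nitrogen], means.loc[der, nitrogen])
            rows.append((name, nitrogen, loss))
            a = wide[(anc, nitrogen)].to_numpy()
            d = wide[(der, nitrogen)].to_numpy()
            ok = np.isfinite(a) & np.isfinite(d) & (a > 0) & (d > 0)
            per_gene_losses[(name, nitrogen)] = np.where(
                d[ok] <= a[ok], 1.0 - d[ok] / a[ok], a[ok] / d[ok] - 1.0
            )
        both = compose_losses(
            rows[-2][2] if rows[-2][0] == "lpd" else rows[-1][2],
            rows[-1][2] if rows[-1][0] == "lsd" else rows[-2][2],
        )
        rows.append(("both", nitrogen, both))
    losses = pd.DataFrame(rows, columns=["transition", "nitrogen", "loss"])

    mw = {}
    for nitrogen in NITROGEN_LEVELS:
        _, p = mann_whitney_u(
            per_gene_losses[("lpd", nitrogen)], per_gene_losses[("lsd", nitrogen)]
        )
        mw[f"lpd_vs_lsd_{nitrogen}"] = p
    for name in transitions:
        _, p = mann_whitney_u(
            per_gene_losses[(name, "high")], per_gene_losses[(name, "low")]
        )
        mw[f"{name}_high_vs_low"] = p
    return {"means": means, "losses": losses, "mw_pvalues": mw}
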