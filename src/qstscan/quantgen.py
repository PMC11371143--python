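"""Per-gene variance components, heritability, and expression Q_ST.

The full model for normalized expression Y of one gene is

    Y = S + G(S) + N + SxN + GxN(S) + eps

with taxon (S), genotype nested in taxon (G), nitrogen level (N) and the two
interactions all random, plus a fixed intercept. Components are estimated by
REML on the dense covariance V = sum_k sigma2_k K_k + sigma2_e I, where each
K_k is the boolean same-level kernel of factor k; the optimizer is L-BFGS-B
with analytic gradients and box constraints at zero, so negative components
are clamped by construction. A Haseman-Elston-style method-of-moments
regression of centered cross-products on the kernels provides starting values
and a fallback when REML fails.

Broad-sense heritability is H2 = (V_S + V_G) / V_A with
V_A = V_S + V_G + V_N + V_SxN/n + V_GxN/n + V_e/n (n = number of nitrogen
levels), and expression Q_ST for a taxon pair at one nitrogen level comes from
the reduced model Y = S + G(S) + eps as V_S / (V_S + V_G) — the between- to
within-taxon variance ratio as used in the scan (not the classical
V_B/(V_B + 2 V_W) form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .datatypes import NITROGEN_LEVELS, PAIRS, TAXA

FULL_COMPONENTS = ("v_s", "v_g", "v_n", "v_sxn", "v_gxn", "v_e")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _same_level_kernel(codes: np.ndarray) -> np.ndarray:
    return (codes[:, None] == codes[None, :]).astype(float)


def full_model_kernels(samples: pd.DataFrame) -> list[np.ndarray]:
    """Same-level kernels for S, G(S), N, SxN, GxN(S), in sample order."""
    taxon = pd.Categorical(samples["taxon"], categories=TAXA).codes
    geno, _ = pd.factorize(samples["genotype_id"])
    nitro = pd.Categorical(samples["nitrogen"], categories=NITROGEN_LEVELS).codes
    return [
        _same_level_kernel(taxon),
        _same_level_kernel(geno),
        _same_level_kernel(nitro),
        _same_level_kernel(taxon * 2 + nitro),
        _same_level_kernel(geno * 2 + nitro),
    ]


def reduced_model_kernels(samples: pd.DataFrame) -> list[np.ndarray]:
    """Kernels for the 2-taxon reduced model Y = S + G(S) + eps."""
    taxon, _ = pd.factorize(samples["taxon"])
    geno, _ = pd.factorize(samples["genotype_id"])
    return [_same_level_kernel(taxon), _same_level_kernel(geno)]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def moment_estimates(y: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    """Haseman-Elston regression: least squares of centered cross-products on
    the kernels plus identity; negatives clamped to zero."""
    n = len(y)
    yc = y - y.mean()
    prods = np.outer(yc, yc).ravel()
    design = np.column_stack([k.ravel() for k in kernels] + [np.eye(n).ravel()])
    est, *_ = np.linalg.lstsq(design, prods, rcond=None)
    return np.clip(est, 0.0, None)


def _reml_nll_grad(sigma2: np.ndarray, y: np.ndarray, kernels: list[np.ndarray]):
    """Negative REML log-likelihood and gradient wrt the variance vector
    (kernel components then residual)."""
    n = len(y)
    v = sigma2[-1] * np.eye(n)
    for s2, k in zip(sigma2[:-1], kernels):
        v += s2 * k
    with np.errstate(all="ignore"):
        try:
            cf = linalg.cho_factor(v, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(sigma2)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
        a = vinv.sum(axis=1)  # V^-1 1
        c = a.sum()  # 1' V^-1 1
        if not np.isfinite(c) or c <= 0:
            return np.inf, np.zeros_like(sigma2)
        p = vinv - np.outer(a, a) / c
        py = p @ y
        nll = 0.5 * (logdet + np.log(c) + y @ py)
        if not np.isfinite(nll):
            return np.inf, np.zeros_like(sigma2)
        grad = np.empty_like(sigma2)
        for i, k in enumerate(kernels):
            grad[i] = 0.5 * (np.sum(p * k) - py @ (k @ py))
        grad[-1] = 0.5 * (np.trace(p) - py @ py)
    return nll, grad


def reml_fit(
    y: np.ndarray, kernels: list[np.ndarray], tol: float = 1e-8
) -> tuple[np.ndarray, str]:
    """REML variance components (kernels + residual).

    Returns (sigma2, status) with status in {"converged", "clamped", "failed"};
    "clamped" means at least one component sits on the zero bound. Falls back
    to the method-of-moments estimates when the optimizer fails.
    """
    y = np.asarray(y, dtype=float)
    var = y.var()
    k = len(kernels) + 1
    if var <= 0:
        return np.zeros(k), "converged"
    scale = var
    ys = y / np.sqrt(scale)

    start = moment_estimates(ys, kernels)
    start = np.clip(start, 1e-4, None)
    res = optimize.minimize(
        _reml_nll_grad,
        start,
        args=(ys, kernels),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * k,
        options={"maxiter": 200, "ftol": tol},
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        est = moment_estimates(ys, kernels) * scale
        return est, "failed"
    est = res.x * scale
    est[est < 1e-12 * scale] = 0.0
    status = "clamped" if np.any(est == 0.0) else "converged"
    return est, status


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class VarCompResult:
    gene_id: str
    v_s: float
    v_g: float
    v_n: float
    v_sxn: float
    v_gxn: float
    v_e: float
    h2: float
    sxn_frac: float
    fit_status: str

    def components(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FULL_COMPONENTS}


def heritability(components: dict[str, float], n_levels: int = 2) -> float:
    """H2 = (V_S + V_G) / V_A; 0 when V_A = 0."""
    va = (
        components["v_s"]
        + components["v_g"]
        + components["v_n"]
        + components["v_sxn"] / n_levels
        + components["v_gxn"] / n_levels
        + components["v_e"] / n_levels
    )
    if va == 0.0:
        return 0.0
    return (components["v_s"] + components["v_g"]) / va


def sxn_fraction(components: dict[str, float]) -> float:
    """Share of total variance carried by the taxon x nitrogen interaction."""
    total = sum(components[name] for name in FULL_COMPONENTS)
    if total == 0.0:
        return 0.0
    return components["v_sxn"] / total


def _design_complete(samples: pd.DataFrame) -> bool:
    present = samples.groupby(["taxon", "nitrogen"]).size()
    cells = {(t, n) for t in TAXA for n in NITROGEN_LEVELS}
    return set(present.index) == cells


def fit_full_model(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    gene: str,
    kernels: list[np.ndarray] | None = None,
) -> VarCompResult:
    """Fit the six-component model for one gene.

    An incomplete design (a taxon x nitrogen cell absent) yields
    fit_status="failed" with NaN statistics rather than an exception.
    """
    cols = samples["sample_id"].to_numpy()
    if kernels is None:
        if not _design_complete(samples):
            return VarCompResult(gene, *([np.nan] * 6), np.nan, np.nan, "failed")
        kernels = full_model_kernels(samples)
    y = norm.loc[gene, cols].to_numpy(dtype=float)
    est, status = reml_fit(y, kernels)
    comps = dict(zip(FULL_COMPONENTS, est))
    return VarCompResult(
        gene,
        *est,
        h2=heritability(comps),
        sxn_frac=sxn_fraction(comps),
        fit_status=status,
    )


def fit_variance_components(
    norm: pd.DataFrame, samples: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Fit the full model for every gene; per-gene fits are independent."""
    if not _design_complete(samples):
        raise ValueError("all taxon x nitrogen cells must be present")
    kernels = full_model_kernels(samples)
    genes = norm.index if genes is None else genes
    rows = [fit_full_model(norm, samples, g, kernels=kernels) for g in genes]
    return pd.DataFrame([r.__dict__ for r in rows])


def fit_qst(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    gene: str,
    pair: str,
    nitrogen: str,
    _cache: dict | None = None,
) -> float:
    """Expression Q_ST = V_S/(V_S + V_G) from the reduced model on one
    nitrogen condition and taxon pair; NaN when undefined."""
    taxa = PAIRS[pair]
    sub = samples[(samples["taxon"].isin(taxa)) & (samples["nitrogen"] == nitrogen)]
    if sub["taxon"].nunique() < 2:
        return float("nan")
    if (sub.groupby("taxon")["genotype_id"].nunique() < 2).any():
        return float("nan")
    if _cache is not None and "kernels" in _cache:
        kernels = _cache["kernels"]
    else:
        kernels = reduced_model_kernels(sub)
        if _cache is not None:
            _cache["kernels"] = kernels
    y = norm.loc[gene, sub["sample_id"].to_numpy()].to_numpy(dtype=float)
    est, status = reml_fit(y, kernels)
    v_s, v_g = est[0], est[1]
    if status == "failed" or v_s + v_g == 0.0:
        return float("nan")
    return float(v_s / (v_s + v_g))


def qst_table(norm: pd.DataFrame, samples: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Q_ST for all genes over the six (pair, nitrogen) comparisons."""
    genes = norm.index if genes is None else genes
    rows = []
    for pair in PAIRS:
        for nitrogen in NITROGEN_LEVELS:
            cache: dict = {}
            for gene in genes:
                q = fit_qst(norm, samples, gene, pair, nitrogen, _cache=cache)
                rows.append((gene, pair, nitrogen, q))
    return pd.DataFrame(rows, columns=["gene_id", "pair", "nitrogen", "qst"])
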