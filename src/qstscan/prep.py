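"""Expression filtering and normalization.

Weakly expressed genes are removed with the CPM rule applied separately per
taxon (>= 1 count per million in >= 10 samples of the same taxon), and the
retained sets are unioned. Normalization defaults to log2(CPM + 1): a
non-negative, variance-flattening, monotone transform that stands in for
model-based variance-stabilizing transforms while keeping the positivity the
downstream coefficient-of-variation statistics require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import validate_counts, validate_samples


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts / library size * 1e6 per sample (column)."""
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"zero library size for sample(s): {zero}")
    return counts / lib * 1e6


@dataclass
class GeneFilterResult:
    """Retained genes per taxon plus their union (in original gene order)."""

    per_taxon: dict[str, pd.Index]
    union: pd.Index


def filter_genes(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 10,
) -> GeneFilterResult:
    """Per-taxon CPM filter: keep a gene for a taxon iff it has CPM >= min_cpm
    in at least min_samples samples of that taxon; the downstream matrix is
    the union across taxa."""
    validate_counts(counts, samples)
    validate_samples(samples)
    c = cpm(counts)
    per_taxon: dict[str, pd.Index] = {}
    keep_any = np.zeros(len(counts), dtype=bool)
    for taxon, grp in samples.groupby("taxon", sort=False):
        cols = [s for s in grp["sample_id"] if s in counts.columns]
        if len(cols) < min_samples:
            raise ValueError(
                f"taxon {taxon!r} has {len(cols)} samples, fewer than min_samples={min_samples}"
            )
        ok = (c[cols] >= min_cpm).sum(axis=1) >= min_samples
        per_taxon[taxon] = counts.index[ok]
        keep_any |= ok.to_numpy()
    return GeneFilterResult(per_taxon=per_taxon, union=counts.index[keep_any])


_TRANSFORMS = {
    "log2cpm1": lambda c: np.log2(c + 1.0),
    "ln_cpm1": lambda c: np.log(c + 1.0),
}


def normalize(counts: pd.DataFrame, transform: str = "log2cpm1") -> pd.DataFrame:
    """Normalize counts to a non-negative log-like expression scale.

    transform: "log2cpm1" (default) -> log2(CPM + 1); "ln_cpm1" -> ln(CPM + 1).
    Both are strictly increasing in the count for a fixed library size.
    """
    try:
        f = _TRANSFORMS[transform]
    except KeyError:
        raise ValueError(
            f"unknown transform {transform!r}; available: {sorted(_TRANSFORMS)}"
        ) from None
    return f(cpm(counts))
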