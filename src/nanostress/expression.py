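"""Benjamini-Hochberg FDR adjustment and differential-expression filtering.

The expression stage consumes per-gene test results from an upstream count
model (gene id, baseMean = average normalized read count, log2 fold change,
raw p-value), adjusts the p-values with the Benjamini-Hochberg step-up
procedure and applies the study-style gene filter: adjusted significance
(padj < 0.05), adequate expression (baseMean above an explicit floor) and,
optionally, a raw p-value cap and a linear fold-change band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "Direction",
    "benjamini_hochberg",
    "filter_de_genes",
    "classify_direction",
    "DE_COLUMNS",
]

DE_COLUMNS = ("gene_id", "baseMean", "log2FoldChange", "pvalue")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort p ascending with stable ranks, set ``q(i) = p(i) * m / i``, enforce
    monotonicity by a cumulative minimum from the largest rank down, cap at 1
    and return in the original order.  Guarantees ``p <= padj <= 1`` and that
    re-sorting by p gives a non-decreasing padj sequence.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the DE-gene filter.

    ``basemean_min`` has no universal value (what counts as "high" expression
    depends on sequencing depth) and must be set explicitly.  ``padj_max``
    is exclusive (padj < padj_max), ``basemean_min`` inclusive.  The optional
    fold band is on the linear scale and applied to ``2**|log2fc|``.
    """

    basemean_min: float
    padj_max: float = 0.05
    pvalue_max: float | None = None
    fold_min: float | None = None
    fold_max: float | None = None

    def __post_init__(self) -> None:
        if self.basemean_min is None:
            raise ValueError("basemean_min must be set explicitly (no default)")
        if self.padj_max <= 0 or self.basemean_min < 0:
            raise ValueError("thresholds must be positive")
        if self.pvalue_max is not None and not (0 < self.pvalue_max <= 1):
            raise ValueError("pvalue_max must lie in (0, 1]")
        if (self.fold_min is None) != (self.fold_max is None):
            raise ValueError("fold_min and fold_max must be set together")
        if self.fold_min is not None and not (0 < self.fold_min <= self.fold_max):
            raise ValueError("fold band must satisfy 0 < fold_min <= fold_max")


class Direction(NamedTuple):
    label: str  # up | down | unchanged
    fold: float  # linear fold change 2**log2fc


def classify_direction(log2fc: float) -> Direction:
    """Direction of regulation and linear fold change from a log2 fold change."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if log2fc > 0:
        label = "up"
    elif log2fc < 0:
        label = "down"
    else:
        label = "unchanged"
    return Direction(label=label, fold=float(2.0**log2fc))


def filter_de_genes(records: pd.DataFrame, config: FilterConfig) -> tuple[pd.DataFrame, dict]:
    """Apply the DE-gene filter and count passing genes by direction.

    ``records`` needs columns ``gene_id``, ``baseMean``, ``log2FoldChange``
    and ``pvalue``; ``padj`` is computed by :func:`benjamini_hochberg` over
    all rows if absent.  A gene passes iff padj < padj_max, baseMean >=
    basemean_min, and (when configured) pvalue < pvalue_max and
    ``2**|log2fc|`` within [fold_min, fold_max].  Returns the passing rows
    (with padj populated) and direction counts over them.
    """
    missing = [c for c in DE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"DE table is missing columns {missing}")
    df = records.copy()
    if (df["baseMean"] < 0).any():
        raise ValueError("baseMean must be non-negative")
    if "padj" not in df.columns or df["padj"].isna().all():
        df["padj"] = benjamini_hochberg(df["pvalue"].to_numpy())
    mask = (df["padj"] < config.padj_max) & (df["baseMean"] >= config.basemean_min)
    if config.pvalue_max is not None:
        mask &= df["pvalue"] < config.pvalue_max
    if config.fold_min is not None:
        fold = np.power(2.0, np.abs(df["log2FoldChange"].to_numpy(dtype=float)))
        mask &= (fold >= config.fold_min) & (fold <= config.fold_max)
    passing = df[mask].copy()
    lfc = passing["log2FoldChange"]
    counts = {
        "up": int((lfc > 0).sum()),
        "down": int((lfc < 0).sum()),
        "unchanged": int((lfc == 0).sum()),
        "total": int(len(passing)),
    }
    return passing, counts
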