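"""Cell-shape statistics: per-group morphometry summaries, unpaired t-tests
and percent changes.

Input tables are tidy pandas DataFrames with one row per measured cell and
columns ``cell_id``, ``group``, ``length`` (um), ``width`` (um) and optionally
``wall_thickness`` (nm).  The length-to-width aspect ratio is computed per
cell and then averaged, matching a per-cell measurement protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "MEASURES",
    "validate_morphometry",
    "summarize_morphometry",
    "unpaired_t_test",
    "percent_change",
    "significance_stars",
]

MEASURES = ("aspect_ratio", "wall_thickness", "length", "width")

_REQUIRED_COLUMNS = ("cell_id", "group", "length", "width")


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, SD (n-1 denominator) and SEM of one measure in one group."""

    group: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    """Two-sided unpaired t-test result."""

    statistic: float
    df: float
    pvalue: float
    method: str

    @property
    def stars(self) -> str:
        return significance_stars(self.pvalue)


def significance_stars(p: float) -> str:
    """Conventional significance marks: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def validate_morphometry(table: pd.DataFrame, groups: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Check a morphometry table and return it unchanged.

    Enforces required columns, strictly positive widths, length >= width,
    positive wall thickness where present, and (optionally) that group labels
    come from a declared set.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"morphometry table is missing columns {missing}")
    if not (table["width"] > 0).all():
        raise ValueError("all widths must be strictly positive")
    if not (table["length"] >= table["width"]).all():
        raise ValueError("length must be >= width for every cell")
    if "wall_thickness" in table.columns:
        wt = table["wall_thickness"].dropna()
        if not (wt > 0).all():
            raise ValueError("wall_thickness must be strictly positive where present")
    if groups is not None:
        unknown = set(table["group"]) - set(groups)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return table


def _measure_values(table: pd.DataFrame, measure: str) -> pd.Series:
    if measure == "aspect_ratio":
        return table["length"] / table["width"]
    if measure not in table.columns:
        raise ValueError(f"measure column {measure!r} not present in table")
    return table[measure]


def summarize_morphometry(table: pd.DataFrame, measure: str = "aspect_ratio") -> dict[str, GroupSummary]:
    """Per-group n/mean/SD/SEM of a measure.

    ``measure`` is one of ``aspect_ratio`` (length/width computed per cell),
    ``wall_thickness``, ``length`` or ``width``.  Missing values are excluded
    pairwise.  Groups with fewer than two non-missing records are rejected by
    name.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    validate_morphometry(table)
    values = _measure_values(table, measure)
    out: dict[str, GroupSummary] = {}
    for group, idx in table.groupby("group", sort=True).groups.items():
        v = values.loc[idx].dropna().to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 records with {measure!r}")
        out[str(group)] = GroupSummary(
            group=str(group), n=len(v), mean=float(np.mean(v)), sd=float(np.std(v, ddof=1))
        )
    return out


def _as_summary(x, label: str) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError(f"group {label} needs >= 2 raw values or a GroupSummary")
    return GroupSummary(group=label, n=len(v), mean=float(np.mean(v)), sd=float(np.std(v, ddof=1)))


def unpaired_t_test(a, b, method: str = "student") -> TestResult:
    """Two-sided unpaired t-test between two groups.

    Each group may be raw values or a :class:`GroupSummary`, so results
    reported only as mean +/- SD with n are directly testable.  ``student``
    uses the pooled-variance statistic with df = n1 + n2 - 2; ``welch`` uses
    the Welch-Satterthwaite approximation.  If both groups have zero variance
    and equal means, the degenerate result t = 0, p = 1 is returned by
    convention.
    """
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    sa, sb = _as_summary(a, "a"), _as_summary(b, "b")
    if sa.sd < 0 or sb.sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if sa.sd == 0.0 and sb.sd == 0.0 and sa.mean == sb.mean:
        df = sa.n + sb.n - 2 if method == "student" else float(sa.n + sb.n - 2)
        return TestResult(statistic=0.0, df=float(df), pvalue=1.0, method=method)
    res = stats.ttest_ind_from_stats(
        mean1=sa.mean, std1=sa.sd, nobs1=sa.n,
        mean2=sb.mean, std2=sb.sd, nobs2=sb.n,
        equal_var=(method == "student"),
    )
    if method == "student":
        df = float(sa.n + sb.n - 2)
    else:  # Welch-Satterthwaite
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    return TestResult(statistic=float(res.statistic), df=df, pvalue=float(res.pvalue), method=method)


def percent_change(reference_mean: float, new_mean: float) -> float:
    """Relative change ``100 * (new - reference) / reference`` in percent."""
    if reference_mean == 0:
        raise ValueError("reference_mean must be non-zero")
    return 100.0 * (new_mean - reference_mean) / reference_mean
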