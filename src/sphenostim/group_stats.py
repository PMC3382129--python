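"""Group summaries (mean ± SEM) and two-sided Mann-Whitney comparisons.

The Mann-Whitney U test uses the exact permutation distribution when
both samples are small (min(n, m) <= 8) and tie-free, otherwise the
normal approximation with midrank tie correction and continuity
correction. Two-sided p doubles the smaller one-sided tail, capped at
1. No multiple-testing correction is applied.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MannWhitneyResult", "mann_whitney_u", "summarize", "compare_groups"]


class MannWhitneyResult(NamedTuple):
    u: float
    p_value: float
    method: str


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns the U statistic for ``x`` (number of (x, y) pairs with
    x > y, ties counted half) and the two-sided p-value. Exact
    permutation p when ``min(n, m) <= 8`` and there are no ties,
    normal approximation with tie and continuity correction otherwise;
    the method used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if np.ptp(combined) == 0:
        # every observation identical: the test is degenerate
        return MannWhitneyResult(u=x.size * y.size / 2.0, p_value=1.0, method="degenerate")
    if not has_ties and min(x.size, y.size) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), method=method)


def summarize(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group n, mean and SEM (sample SD with n-1 denominator / sqrt(n))."""
    rows = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append(dict(group=label, n=int(v.size), mean=float(v.mean()), sem=sem))
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    group_col: str,
    value_col: str,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons on a long-format table.

    When ``pairs`` is omitted every unordered pair of groups is
    compared. Returns one row per pair with n's, U and two-sided p.
    """
    groups = {g: sub[value_col].to_numpy() for g, sub in table.groupby(group_col)}
    if pairs is None:
        labels = sorted(groups)
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValueError(f"unknown group in pair ({a!r}, {b!r})")
        res = mann_whitney_u(groups[a], groups[b])
        rows.append(
            dict(
                group_a=a,
                group_b=b,
                n_a=len(groups[a]),
                n_b=len(groups[b]),
                u=res.u,
                p_value=res.p_value,
                method=res.method,
            )
        )
    return pd.DataFrame(rows)
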