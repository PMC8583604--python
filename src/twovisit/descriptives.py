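"""Group-comparison statistics and descriptive summary tables.

Continuous variables are summarised as median (first, third quartile)
and compared between care groups with the Kruskal–Wallis rank test
(for two groups the large-sample Wilcoxon rank-sum test); categorical
variables are summarised as count (percent) and compared with Pearson's
chi-square test without continuity correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import study

__all__ = [
    "pearson_chi_square",
    "kruskal_wallis",
    "summarize_median_iqr",
    "crosstab_counts",
    "descriptive_table",
]


def pearson_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction is applied, matching the convention needed
    to reproduce standard two-group clinical comparisons.  Expected
    counts below 1 trigger a warning, not an error: small sparse cells
    (e.g. rare treatment categories) are tested as-is.

    Returns ``(statistic, df, p)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols, total = counts.sum(axis=1), counts.sum(axis=0), counts.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column marginal: the test is undefined")
    expected = np.outer(rows, cols) / total
    if (expected < 1).any():
        warnings.warn("expected cell count below 1: chi-square approximation is crude")
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return statistic, df, float(stats.chi2.sf(statistic, df))


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Delegates to :func:`scipy.stats.kruskal`; all-tied samples are the
    degenerate H = 0, p = 1 case by convention.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    keep = ~np.isnan(values)
    values, group_labels = values[keep], group_labels[keep]
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def summarize_median_iqr(values) -> tuple[float, float, float]:
    """(q1, median, q3) by linear interpolation of order statistics."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no non-missing values to summarise")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def crosstab_counts(values, group_labels, categories=None) -> pd.DataFrame:
    """Category x group count table (rows = categories, columns = groups)."""
    s = pd.Series(values)
    keep = s.notna()
    tab = pd.crosstab(s[keep], pd.Series(group_labels)[keep.to_numpy()])
    if categories is not None:
        tab = tab.reindex(list(categories), fill_value=0)
    return tab


def _fmt_miqr(values, decimals=1) -> str:
    q1, med, q3 = summarize_median_iqr(values)
    f = f"%.{decimals}f"
    return f"{f % med} ({f % q1}, {f % q3})"


def descriptive_table(
    data: pd.DataFrame,
    variables: list[tuple[str, str]],
    group_col: str = "group",
    decimals: int = 1,
) -> pd.DataFrame:
    """Clinical "table one": one block per variable, groups side by side.

    ``variables`` is a list of ``(column, kind)`` with kind
    ``"continuous"`` or ``"categorical"``.  Continuous rows show
    median (q1, q3) with a Kruskal–Wallis p-value; categorical blocks
    show count (percent) per category with a Pearson chi-square
    p-value on the full contingency table.
    """
    groups = [g for g in study.GROUP_LABELS if g in set(data[group_col])]
    if not groups:
        groups = sorted(pd.unique(data[group_col]))
    rows = []
    for col, kind in variables:
        s = data[col]
        n = int(s.notna().sum())
        if kind == "continuous":
            vals = {"All": s}
            for g in groups:
                vals[g] = s[data[group_col] == g]
            try:
                _, p = kruskal_wallis(s.to_numpy(dtype=float), data[group_col].to_numpy())
                p = round(p, 3)
            except ValueError:  # a group with no non-missing values
                p = np.nan

            def fmt(v):
                v = v.to_numpy(dtype=float)
                return _fmt_miqr(v, decimals) if np.isfinite(v).any() else ""

            rows.append(
                {
                    "variable": col,
                    "category": "",
                    "N": n,
                    **{g: fmt(vals[g]) for g in groups},
                    "All": fmt(s),
                    "p_value": p,
                }
            )
        elif kind == "categorical":
            tab = crosstab_counts(s, data[group_col])
            tab = tab[[g for g in groups if g in tab.columns]]
            _, _, p = pearson_chi_square(tab.to_numpy())
            rows.append(
                {"variable": col, "category": "", "N": n, **{g: "" for g in groups}, "All": "", "p_value": round(p, 3)}
            )
            all_counts = tab.sum(axis=1)
            for cat in tab.index:
                row = {"variable": "", "category": str(cat), "N": "", "p_value": ""}
                for g in groups:
                    cnt = int(tab.loc[cat, g])
                    row[g] = f"{cnt} ({100 * cnt / tab[g].sum():.0f}%)"
                row["All"] = f"{int(all_counts[cat])} ({100 * all_counts[cat] / n:.0f}%)"
                rows.append(row)
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows, columns=["variable", "category", "N", *groups, "All", "p_value"])
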