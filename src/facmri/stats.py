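"""Nonparametric group and depot comparisons of per-subject FAC summaries.

Between-group contrasts use the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test; within-group depot contrasts use the two-sided
Wilcoxon signed-rank test on pairwise-complete subjects.  Small samples
(combined n <= 12, no ties) use the exact null distribution; larger or
tied samples use the normal approximation with tie and continuity
corrections.  Summaries are medians with interquartile ranges
(linear-interpolation quartiles); the group difference is the difference
of group medians.  p-values are reported raw, with no multiple-testing
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "rank_sum_test",
    "signed_rank_test",
    "depot_comparison_table",
    "FAC_PARAMETERS",
]

FAC_PARAMETERS = ("fsfa", "fmufa", "fpufa", "ndb", "nmidb")
_EXACT_N = 12


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sided nonparametric comparison."""

    test_name: str
    method: str  # "exact" or "normal_approx"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    median_diff: float  # median_b - median_a

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _summary(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), (float(q1), float(q3))


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < x.size


def rank_sum_test(values_a, values_b) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups.

    The statistic is the Mann-Whitney U of sample *a*.  Samples with all
    values identical across both groups give p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all observations identical; rank-sum p set to 1")
        u = a.size * b.size / 2.0
        method, p = "degenerate", 1.0
    else:
        pooled = np.concatenate([a, b])
        exact = (a.size + b.size) <= _EXACT_N and not _has_ties(pooled)
        method = "exact" if exact else "normal_approx"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        u, p = float(res.statistic), float(res.pvalue)
    med_a, iqr_a = _summary(a)
    med_b, iqr_b = _summary(b)
    return ComparisonResult(
        "wilcoxon_rank_sum", method, u, min(p, 1.0),
        a.size, b.size, med_a, med_b, iqr_a, iqr_b, med_b - med_a,
    )


def signed_rank_test(paired_a, paired_b) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank comparison of paired samples.

    Zero differences are dropped before ranking.  All-zero differences give
    p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; signed-rank p set to 1")
        w, p, method = 0.0, 1.0, "degenerate"
    elif nonzero.size < 2:
        warnings.warn("fewer than 2 nonzero differences; signed-rank p set to 1")
        w, p, method = 0.0, 1.0, "degenerate"
    else:
        exact = nonzero.size <= _EXACT_N and not _has_ties(np.abs(nonzero))
        method = "exact" if exact else "normal_approx"
        res = sps.wilcoxon(
            nonzero,
            alternative="two-sided",
            zero_method="wilcox",
            correction=not exact,
            method="exact" if exact else "approx",
        )
        w, p = float(res.statistic), float(res.pvalue)
    med_a, iqr_a = _summary(a)
    med_b, iqr_b = _summary(b)
    return ComparisonResult(
        "wilcoxon_signed_rank", method, w, min(p, 1.0),
        a.size, b.size, med_a, med_b, iqr_a, iqr_b, med_b - med_a,
    )


def _result_row(base: dict, res: ComparisonResult) -> dict:
    row = dict(base)
    row.update(
        test=res.test_name,
        method=res.method,
        statistic=res.statistic,
        p_value=res.p_value,
        n_a=res.n_a,
        n_b=res.n_b,
        median_a=res.median_a,
        median_b=res.median_b,
        q1_a=res.iqr_a[0], q3_a=res.iqr_a[1],
        q1_b=res.iqr_b[0], q3_b=res.iqr_b[1],
        median_diff=res.median_diff,
    )
    return row


def _validate_table(table: pd.DataFrame) -> None:
    required = {"subject", "group", "depot", *FAC_PARAMETERS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table lacks columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("subject table is empty")
    if table.duplicated(["subject", "depot"]).any():
        raise ValueError("duplicate (subject, depot) rows")
    frac_sum = table[["fsfa", "fmufa", "fpufa"]].sum(axis=1)
    if not np.allclose(frac_sum, 1.0, atol=1e-6):
        raise ValueError("fsfa + fmufa + fpufa must sum to 1 per row")


_DEPOT_PAIRS = (("sat", "vat"), ("ssat", "dsat"))


def depot_comparison_table(
    table: pd.DataFrame,
    *,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Full comparison battery over a per-subject depot summary table.

    Input rows are keyed by (subject, group, depot) with columns
    fsfa/fmufa/fpufa/ndb/nmidb.  For every depot and parameter the two
    groups are compared by rank-sum (difference reported as
    median(group_b) - median(group_a)); within each group, SAT vs VAT and
    sSAT vs dSAT are compared by signed-rank on subjects with both depots
    (subjects missing a depot are excluded pairwise).  Output is one tidy
    row per comparison with raw p-values.
    """
    _validate_table(table)
    groups = list(pd.unique(table["group"]))
    if group_order is not None:
        groups = [g for g in group_order if g in groups]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    depots = list(pd.unique(table["depot"]))
    rows: list[dict] = []

    for depot in depots:
        sub = table[table["depot"] == depot]
        xa = sub[sub["group"] == ga]
        xb = sub[sub["group"] == gb]
        for param in FAC_PARAMETERS:
            res = rank_sum_test(xa[param].to_numpy(), xb[param].to_numpy())
            rows.append(
                _result_row(
                    {
                        "comparison": "between_groups",
                        "group_a": ga, "group_b": gb,
                        "depot_a": depot, "depot_b": depot,
                        "parameter": param,
                    },
                    res,
                )
            )

    for group in groups:
        sub = table[table["group"] == group]
        for depot_a, depot_b in _DEPOT_PAIRS:
            wide = sub[sub["depot"].isin([depot_a, depot_b])]
            if wide["depot"].nunique() < 2:
                continue
            pivot = wide.pivot(index="subject", columns="depot")
            for param in FAC_PARAMETERS:
                pair = pivot[param][[depot_a, depot_b]].dropna()
                if len(pair) < 2:
                    continue
                res = signed_rank_test(
                    pair[depot_a].to_numpy(), pair[depot_b].to_numpy()
                )
                rows.append(
                    _result_row(
                        {
                            "comparison": "between_depots",
                            "group_a": group, "group_b": group,
                            "depot_a": depot_a, "depot_b": depot_b,
                            "parameter": param,
                        },
                        res,
                    )
                )
    return pd.DataFrame(rows)
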