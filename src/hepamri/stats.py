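"""Cohort statistics: normality-gated two-group comparison with rank
sums, and the Spearman rank-correlation matrix across MRI, histology and
biochemical parameters.

The comparison mirrors the standard small-cohort workflow: each group is
tested for normality with Shapiro-Wilk; if both pass, an equal-variance
two-sided t-test is used, otherwise the Mann-Whitney U test with
mid-ranks for ties, reporting per-group sums of pooled ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "CorrelationMatrix", "compare_groups",
           "spearman_matrix", "compare_table"]


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-group comparison."""

    parameter_name: str
    test_used: str                      # "t-test" | "mann-whitney"
    p_value: float
    statistic: float
    group_summaries: tuple[float, float]   # means (t-test) or medians (U test)
    rank_sums: tuple[float, float] | None  # per-group sums of pooled ranks
    shapiro_p: tuple[float, float] | None


def _rank_sums(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    ranks = sps.rankdata(np.concatenate([a, b]))   # mid-ranks on ties
    return float(ranks[:len(a)].sum()), float(ranks[len(a):].sum())


def compare_groups(values_a, values_b, normality_alpha: float = 0.05,
                   parameter_name: str = "", equal_var: bool = True,
                   force_test: str = "auto") -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups must have >= 3 values.  If both pass Shapiro-Wilk at
    ``normality_alpha``, a two-sided two-sample t-test (equal variance by
    default, Welch with ``equal_var=False``) is applied and group means
    reported; otherwise the two-sided Mann-Whitney U test with mid-ranks,
    reporting medians and per-group rank sums.  Degenerate all-equal
    pooled data yields p = 1 with mid-rank rank sums.

    ``force_test="mann-whitney"`` bypasses the gate — appropriate for
    ordinal variables such as histology scores, which are rank-tested
    regardless of distribution; ``"t-test"`` forces the parametric path.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values for the normality gate")
    if force_test not in ("auto", "t-test", "mann-whitney"):
        raise ValueError(f"unknown force_test {force_test!r}")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupComparison(parameter_name, "mann-whitney", 1.0, np.nan,
                               (float(np.median(a)), float(np.median(b))),
                               _rank_sums(a, b), None)

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:          # constant within group: not normal
            return 0.0
        return float(sps.shapiro(x).pvalue)

    p_a, p_b = _shapiro_p(a), _shapiro_p(b)
    use_t = (p_a > normality_alpha and p_b > normality_alpha) \
        if force_test == "auto" else (force_test == "t-test")
    if use_t:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(parameter_name, "t-test", float(res.pvalue),
                               float(res.statistic),
                               (float(a.mean()), float(b.mean())),
                               None, (p_a, p_b))
    # exact p for small tie-free samples, normal approximation with tie
    # correction otherwise (scipy's "auto" policy)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(parameter_name, "mann-whitney", float(res.pvalue),
                           float(res.statistic),
                           (float(np.median(a)), float(np.median(b))),
                           _rank_sums(a, b), (p_a, p_b))


@dataclass
class CorrelationMatrix:
    """Spearman coefficients, p-values and significance flags; rows are
    outcome variables, columns the MRI/kinetic parameters."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    holm_significant: pd.DataFrame | None = None


def spearman_matrix(table: pd.DataFrame, row_vars: list[str],
                    col_vars: list[str], alpha: float = 0.05,
                    holm: bool = False) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations with pairwise deletion.

    Every (row, column) pair needs >= 5 complete observations.  Mid-ranks
    are used on ties; p-values are two-sided.  With ``holm=True`` an
    additional Holm-adjusted significance table is attached (off by
    default: the primary analysis reports per-test p at ``alpha``).
    """
    r = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    p = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    for rv in row_vars:
        for cv in col_vars:
            pair = table[[rv, cv]].dropna()
            if len(pair) < 5:
                raise ValueError(
                    f"pair ({rv}, {cv}) has {len(pair)} complete observations; need >= 5")
            if rv == cv:
                r.loc[rv, cv], p.loc[rv, cv] = 1.0, 0.0
                continue
            if np.ptp(pair[rv]) == 0 or np.ptp(pair[cv]) == 0:
                # a constant variable has no rank ordering to correlate
                r.loc[rv, cv], p.loc[rv, cv] = np.nan, np.nan
                continue
            res = sps.spearmanr(pair[rv], pair[cv])
            r.loc[rv, cv] = float(res.statistic)
            p.loc[rv, cv] = float(res.pvalue)
    sig = p < alpha
    holm_sig = None
    if holm:
        flat = p.to_numpy().ravel()
        order = np.argsort(flat)
        m = len(flat)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * flat[i])
            adj[i] = min(running, 1.0)
        holm_sig = pd.DataFrame(adj.reshape(p.shape) < alpha,
                                index=p.index, columns=p.columns)
    return CorrelationMatrix(r=r, p=p, significant=sig, alpha=alpha,
                             holm_significant=holm_sig)


def compare_table(table: pd.DataFrame, group_col: str,
                  value_cols: list[str] | None = None,
                  normality_alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison of every parameter column; one row per parameter.

    ``table`` holds one row per animal with a two-level ``group_col``.
    Parameters whose comparison fails (e.g. too few animals) are
    reported with the error message rather than aborting the table.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    ga, gb = groups
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in value_cols:
        a = table.loc[table[group_col] == ga, col].dropna()
        b = table.loc[table[group_col] == gb, col].dropna()
        try:
            cmp_res = compare_groups(a, b, normality_alpha, parameter_name=col)
            rows.append({
                "parameter": col, "test": cmp_res.test_used,
                f"{ga}_summary": cmp_res.group_summaries[0],
                f"{gb}_summary": cmp_res.group_summaries[1],
                f"{ga}_rank_sum": cmp_res.rank_sums[0] if cmp_res.rank_sums else np.nan,
                f"{gb}_rank_sum": cmp_res.rank_sums[1] if cmp_res.rank_sums else np.nan,
                "p_value": cmp_res.p_value, "error": "",
            })
        except ValueError as exc:
            rows.append({"parameter": col, "test": "", f"{ga}_summary": np.nan,
                         f"{gb}_summary": np.nan, f"{ga}_rank_sum": np.nan,
                         f"{gb}_rank_sum": np.nan, "p_value": np.nan,
                         "error": str(exc)})
    return pd.DataFrame(rows)
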