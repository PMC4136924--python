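"""Two-branch group comparison for per-cell measurements.

Each group is first checked for normality with Shapiro-Wilk; when both
groups look normal (p >= alpha_norm, default 0.05) the comparison is a
two-sided equal-variance Student's t-test, otherwise a two-sided
Mann-Whitney U test. The Mann-Whitney p-value uses the exact U distribution
when the smaller group has at most 8 values and there are no ties, and the
normal approximation with tie correction otherwise.

The branch taken is never silent: the result carries both normality
p-values, the test name, and the sample sizes, so the choice is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "compare_groups", "compare_table"]

EXACT_MW_MAX_N = 8
DEFAULT_ALPHA_NORM = 0.05


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    normality_p_a: float
    normality_p_b: float
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "group_a": self.label_a,
            "group_b": self.label_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "normality_p_a": self.normality_p_a,
            "normality_p_b": self.normality_p_b,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def _shapiro_p(x: np.ndarray) -> float:
    # constant sample: Shapiro-Wilk undefined; treat as maximally non-normal
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def compare_groups(
    a,
    b,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
    *,
    label_a: str = "a",
    label_b: str = "b",
    equal_var: bool = True,
) -> GroupComparison:
    """Compare two samples of per-cell values with the normality-branched test.

    ``equal_var=False`` switches the t branch to Welch's test. Requires at
    least 3 values per group; two groups with no variance anywhere are a
    degenerate input and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"need n >= 3 per group, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("all values identical in both groups: no test defined")

    p_norm_a = _shapiro_p(a)
    p_norm_b = _shapiro_p(b)
    if p_norm_a >= alpha_norm and p_norm_b >= alpha_norm:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test_used, stat, p = "student_t", float(res.statistic), float(res.pvalue)
    else:
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (min(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test_used, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        test_used=test_used,
        statistic=stat,
        # extreme separations underflow to 0.0; clamp so p stays in (0, 1]
        p_value=min(max(float(p), np.finfo(float).tiny), 1.0),
    )


def compare_table(
    df,
    value: str,
    group_col: str,
    by: list[str] | None = None,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
    fdr: bool = False,
):
    """Pairwise two-group comparison of ``value`` for each stratum in ``by``
    (e.g. per channel), returning a list of result dicts.

    Expects exactly two group labels in ``group_col``. With ``fdr=True`` a
    Benjamini-Hochberg adjusted p-value column is added across strata (off
    by default: single comparisons need no correction).
    """
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    strata = [((), df)] if not by else list(df.groupby(by))
    out = []
    for key, sub in strata:
        a = sub.loc[sub[group_col] == ga, value].dropna().to_numpy()
        b = sub.loc[sub[group_col] == gb, value].dropna().to_numpy()
        cmp = compare_groups(a, b, alpha_norm, label_a=str(ga), label_b=str(gb))
        rec = cmp.as_dict()
        if by:
            key = key if isinstance(key, tuple) else (key,)
            rec.update(dict(zip(by, key)))
        rec["value"] = value
        out.append(rec)
    if fdr and len(out) > 1:
        adj = multipletests([r["p_value"] for r in out], method="fdr_bh")[1]
        for r, q in zip(out, adj):
            r["p_adjusted"] = float(q)
    return out
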