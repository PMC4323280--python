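"""Statistical battery for the concurrent-validity analysis.

The analysis workflow is: (i) internal consistency of the binary risk
indicators via Cronbach's alpha after excluding zero-variance items;
(ii) a Kolmogorov-Smirnov (Lilliefors) normality gate on the sum score and
the global composites; (iii) since normality fails, nonparametric inference
throughout — Spearman rank correlations between the risk sum score and the
global criteria, Mann-Whitney U comparisons of criterion scales between
indicator-positive and indicator-negative women, Kruskal-Wallis H across
hospital units — plus a pooled-variance t-test for interviewer-profession
effects and Pearson chi-square tests for dichotomous subgroup differences.

Conventions: midranks for ties everywhere; the Mann-Whitney U reported is
the first group's U (rank-sum form), with an exact-enumeration p-value for
small untied samples and a tie-corrected normal approximation otherwise;
p-values are two-sided by default with a one-sided option; no
multiple-testing correction is applied (the report annotates the number of
tests run instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ReliabilityResult",
    "CorrelationResult",
    "GroupComparison",
    "NormalityResult",
    "cronbach_alpha",
    "spearman_matrix",
    "mann_whitney",
    "kruskal_wallis",
    "student_t",
    "chi_square_2x2",
    "ks_normality",
    "item_criterion_comparison",
    "descriptives",
]


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    n_items_input: int
    n_items_retained: int
    excluded_items: tuple[tuple[str, str], ...]  # (item, reason)
    n_respondents: int


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    rho: float  # NaN when undefined (constant variable)
    n: int
    p: float


@dataclass(frozen=True)
class GroupComparison:
    test: str  # mann_whitney_u | kruskal_wallis_h | student_t | chi_square
    statistic: float
    p: float
    df: Optional[float] = None
    group_sizes: tuple[int, ...] = ()
    group_summaries: tuple[Mapping[str, float], ...] = ()
    method: str = ""
    sided: str = "two-sided"


@dataclass(frozen=True)
class NormalityResult:
    variable: str
    D: float
    n: int
    p: float
    normal: bool
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(item_matrix: pd.DataFrame) -> ReliabilityResult:
    """Cronbach's alpha over binary (or ordinal) items, after dropping
    zero-variance items.

    Constant items carry no covariance information, so they are excluded
    before the alpha computation and listed in the result; rows with any
    missing value are dropped (complete case).  Alpha is the classical

        alpha = k/(k-1) * (1 - sum of item variances / variance of total)

    with sample (n-1) variances.
    """
    df = item_matrix.astype("float64").dropna(axis=0, how="any")
    n = len(df)
    if n < 2:
        raise ValueError("cronbach_alpha needs >= 2 complete respondents")
    variances = df.var(ddof=1)
    excluded = tuple(
        (str(item), "zero_variation") for item in df.columns[variances == 0.0]
    )
    retained = df.loc[:, variances > 0.0]
    k = retained.shape[1]
    if k < 2:
        raise ValueError(
            f"cronbach_alpha needs >= 2 items with variation, got {k}"
        )
    total_var = retained.sum(axis=1).var(ddof=1)
    alpha = k / (k - 1) * (1.0 - retained.var(ddof=1).sum() / total_var)
    return ReliabilityResult(
        alpha=float(alpha),
        n_items_input=item_matrix.shape[1],
        n_items_retained=k,
        excluded_items=excluded,
        n_respondents=n,
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def spearman_matrix(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> list[CorrelationResult]:
    """Spearman rank correlations for every variable pair, pairwise complete.

    Rho is the product-moment correlation of midranks; each pair reports its
    own pairwise-complete n.  A constant variable yields an undefined rho
    (NaN) rather than an error.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    out: list[CorrelationResult] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = table[[a, b]].astype("float64").dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(
                    f"pair ({a}, {b}) has only {n} complete cases (need >= 3)"
                )
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                out.append(CorrelationResult((a, b), float("nan"), n, float("nan")))
                continue
            rho, p = sps.spearmanr(pair[a], pair[b])
            out.append(CorrelationResult((a, b), float(rho), n, float(p)))
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _rank_summary(x: np.ndarray) -> dict[str, float]:
    return {
        "n": int(x.size),
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def _clean(values) -> np.ndarray:
    x = np.asarray(pd.Series(values, dtype="float64").dropna(), dtype=float)
    return x


def mann_whitney(
    group_a, group_b, *, sided: str = "two-sided", exact_max_n: int = 8
) -> GroupComparison:
    """Mann-Whitney U test between two independent groups.

    The statistic is the first group's U computed from midrank sums,
    ``U_A = R_A - n_A (n_A + 1) / 2``, so ``U_A + U_B = n_A n_B``.  The
    p-value is by exact enumeration of the permutation distribution when
    ``min(n_A, n_B) <= exact_max_n`` and there are no ties, and a
    tie-corrected normal approximation (no continuity correction) otherwise.
    Per-group median/min/max are reported for tabulation.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires two non-empty groups")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if sided not in ("two-sided", "less", "greater"):
        raise ValueError("sided must be 'two-sided', 'less' or 'greater'")
    res = sps.mannwhitneyu(
        a, b, alternative=sided, method=method, use_continuity=False,
    )
    return GroupComparison(
        test="mann_whitney_u",
        statistic=u_a,
        p=float(res.pvalue),
        group_sizes=(int(a.size), int(b.size)),
        group_summaries=(_rank_summary(a), _rank_summary(b)),
        method=method,
        sided=sided,
    )


def kruskal_wallis(groups: Sequence) -> GroupComparison:
    """Kruskal-Wallis H across k >= 2 groups, with tie correction;
    chi-square p on k-1 degrees of freedom."""
    arrays = [_clean(g) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    if np.unique(np.concatenate(arrays)).size < 2:
        # all observations identical: H = 0 by definition
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return GroupComparison(
        test="kruskal_wallis_h",
        statistic=float(h),
        p=float(p),
        df=float(len(arrays) - 1),
        group_sizes=tuple(int(a.size) for a in arrays),
        group_summaries=tuple(_rank_summary(a) for a in arrays),
    )


def student_t(group_a, group_b, *, sided: str = "two-sided") -> GroupComparison:
    """Pooled-variance two-sample t-test; df = n_A + n_B - 2."""
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("student_t requires n >= 2 per group")
    if sided not in ("two-sided", "less", "greater"):
        raise ValueError("sided must be 'two-sided', 'less' or 'greater'")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            raise ValueError(
                "zero within-group variance with unequal means: "
                "t statistic undefined"
            )
    else:
        res = sps.ttest_ind(a, b, equal_var=True, alternative=sided)
        t, p = float(res.statistic), float(res.pvalue)
    df = float(a.size + b.size - 2)
    summaries = tuple(
        {"n": int(x.size), "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
        for x in (a, b)
    )
    return GroupComparison(
        test="student_t", statistic=t, p=p, df=df,
        group_sizes=(int(a.size), int(b.size)),
        group_summaries=summaries, sided=sided,
    )


def chi_square_2x2(table, *, continuity: bool = False) -> GroupComparison:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    Continuity (Yates) correction is off by default; a zero row or column
    margin is an error naming the margin.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi_square_2x2 expects a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    for label, sums in (("row", row_sums), ("column", col_sums)):
        zeros = np.nonzero(sums == 0)[0]
        if zeros.size:
            raise ValueError(f"zero {label} margin at index {int(zeros[0])}")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=continuity)
    return GroupComparison(
        test="chi_square", statistic=float(chi2), p=float(p), df=float(df),
        group_sizes=tuple(int(s) for s in row_sums),
    )


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def ks_normality(
    values, *, variable: str = "variable", alpha: float = 0.05
) -> NormalityResult:
    """Kolmogorov-Smirnov normality test with the Lilliefors correction.

    Mean and SD are estimated from the data, so the plain K-S null
    distribution does not apply; the Lilliefors variant computes
    ``D = sup |empirical CDF - fitted normal CDF|`` and calibrated p-values
    (table/simulation based).  ``normal`` is the verdict at ``alpha``:
    a significant D means the normality assumption is **not** met.
    """
    x = _clean(values)
    if x.size < 4:
        raise ValueError(f"ks_normality needs n >= 4, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError(f"{variable!r} is constant; normality test undefined")
    d, p = lilliefors(x, dist="norm")
    return NormalityResult(
        variable=variable, D=float(d), n=int(x.size), p=float(p),
        normal=bool(p > alpha), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Item-criterion comparisons and descriptives
# ---------------------------------------------------------------------------

def item_criterion_comparison(
    indicator: pd.Series, criteria: pd.DataFrame, *, sided: str = "two-sided"
) -> pd.DataFrame:
    """Mann-Whitney comparison of each criterion scale between
    indicator-positive and indicator-negative respondents.

    ``indicator`` is a boolean series aligned with ``criteria`` (one column
    per criterion scale).  Returns one row per scale with the per-group
    median/min/max, U and p, mirroring the item-validity tables.
    """
    ind = pd.Series(indicator).astype("boolean")
    rows = []
    for col in criteria.columns:
        sub = pd.DataFrame({"flag": ind, "y": criteria[col]}).dropna()
        pos = sub.loc[sub["flag"].astype(bool), "y"]
        neg = sub.loc[~sub["flag"].astype(bool), "y"]
        if pos.empty or neg.empty:
            raise ValueError(
                f"indicator splits {col!r} into an empty group "
                f"(positives={len(pos)}, negatives={len(neg)})"
            )
        cmp = mann_whitney(pos, neg, sided=sided)
        pos_s, neg_s = cmp.group_summaries
        rows.append({
            "scale": col,
            "n_yes": pos_s["n"], "mdn_yes": pos_s["median"],
            "min_yes": pos_s["min"], "max_yes": pos_s["max"],
            "n_no": neg_s["n"], "mdn_no": neg_s["median"],
            "min_no": neg_s["min"], "max_no": neg_s["max"],
            "U": cmp.statistic, "p": cmp.p, "method": cmp.method,
        })
    return pd.DataFrame(rows).set_index("scale")


def descriptives(
    profiles: pd.DataFrame,
    indicator_columns: Sequence[str],
    subgroup: Optional[pd.Series] = None,
    rating_columns: Sequence[str] = (),
    ratings: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Cohort descriptive table: per-indicator N (%) and rating mean (SD),
    overall and by an optional binary subgroup, with a subgroup-difference
    test per row (chi-square for indicators, Mann-Whitney for ratings).

    Raises on an empty cohort.  The subgroup series (e.g. "took part in the
    validation interview") must be boolean and aligned with ``profiles``.
    """
    if len(profiles) == 0:
        raise ValueError("descriptives requires a non-empty cohort")
    n_total = len(profiles)
    rows = []
    for col in indicator_columns:
        x = profiles[col].astype("boolean")
        count = int(x.sum())
        row = {
            "variable": col, "kind": "indicator",
            "n": count, "pct": 100.0 * count / n_total,
        }
        if subgroup is not None:
            g = subgroup.astype(bool)
            for label, mask in (("in", g), ("out", ~g)):
                xs = x[mask]
                row[f"n_{label}"] = int(xs.sum())
                row[f"pct_{label}"] = (
                    100.0 * int(xs.sum()) / len(xs) if len(xs) else float("nan")
                )
            tab = pd.crosstab(g, x.astype(bool)).reindex(
                index=[False, True], columns=[False, True], fill_value=0
            ).to_numpy()
            try:
                row["p_diff"] = chi_square_2x2(tab).p
            except ValueError:
                row["p_diff"] = float("nan")  # degenerate margin
        rows.append(row)
    source = ratings if ratings is not None else profiles
    for col in rating_columns:
        y = source[col].astype("float64")
        row = {
            "variable": col, "kind": "rating",
            "mean": float(y.mean()), "sd": float(y.std(ddof=1)),
        }
        if subgroup is not None:
            g = subgroup.astype(bool)
            row["mean_in"] = float(y[g].mean())
            row["mean_out"] = float(y[~g].mean())
            try:
                row["p_diff"] = mann_whitney(y[g], y[~g]).p
            except ValueError:
                row["p_diff"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
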