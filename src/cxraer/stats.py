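"""The statistical battery used by the radiograph-aeration analysis.

All p-values are two-sided.  Group comparisons of numeric variables use the
heteroscedastic (Welch) t-test; dichotomous variables use Fisher's exact
test with the summed-probabilities two-sided rule; correlations are Pearson
product-moment with the exact t transform; repeated-measures designs use
one-way RM-ANOVA (parametric, Bonferroni post hoc) or the Friedman rank
test (non-parametric, Conover post hoc).

The Conover post hoc follows Conover (1999): with within-block ranks
r_ij, rank sums R_j, A = sum r_ij^2 and B = (1/n) sum_j R_j^2, the pairwise
statistic is t = (R_i - R_j) / sqrt(2n(A - B)/((n-1)(k-1))) on (n-1)(k-1)
df; A - B is exactly the error sum of squares of the two-way rank layout,
so the denominator is the rank-LSD standard error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "welch_t_test",
    "fisher_exact_2x2",
    "pearson_correlation",
    "rm_anova",
    "bonferroni_adjust",
    "friedman_test",
    "conover_posthoc",
    "standard_comparisons",
]


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    n: tuple[int, ...] = ()
    adjusted: bool = False
    adjustment: str = ""
    degenerate: bool = False
    defined: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        a = a[~np.isnan(a)]
    return a


def welch_t_test(x, y) -> TestResult:
    """Two-sided heteroscedastic (Welch) t-test.

    Degenerate zero-variance samples yield p = 1 (equal means) or p = 0,
    flagged, rather than NaN.
    """
    x, y = _as_array(x), _as_array(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t_test needs n >= 2 per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        equal = x.mean() == y.mean()
        return TestResult("welch_t", 0.0 if equal else np.inf, None,
                          1.0 if equal else 0.0, (len(x), len(y)), degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df),
                      float(res.pvalue), (len(x), len(y)))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Two-sided p is the sum of hypergeometric probabilities (same margins)
    of all tables no more probable than the observed one.
    """
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError("table cells must be non-negative integers")
    if sum(cells) < 1:
        raise ValueError("table total must be >= 1")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return TestResult("fisher_exact", float(odds), None, float(p),
                      (a + b, c + d), extras={"table": cells})


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation with OLS slope/intercept.

    p from t = r sqrt((n-2)/(1-r^2)) on n-2 df, two-sided.  Zero variance
    in either variable gives an undefined-r report (not r = 0).
    """
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("pearson_correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("pearson_r", np.nan, n - 2, np.nan, (n,), defined=False)
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return TestResult("pearson_r", float(r), n - 2, float(p), (n,),
                      extras={"slope": float(reg.slope), "intercept": float(reg.intercept)})


def rm_anova(table) -> TestResult:
    """One-way repeated-measures ANOVA on an (n blocks x k treatments) table.

    F = MS_treatment / MS_error with df (k-1), (n-1)(k-1); the full sum of
    squares partition (SS_total = SS_subjects + SS_treatment + SS_error)
    is returned in ``extras``.  Missing cells are an error — no imputation.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("table must be 2-D (blocks x treatments)")
    if np.isnan(X).any():
        raise ValueError("rm_anova requires a complete table (no missing cells)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("rm_anova needs >= 2 blocks and >= 2 treatments")
    grand = X.mean()
    ss_total = float(((X - grand) ** 2).sum())
    ss_subjects = float(k * ((X.mean(axis=1) - grand) ** 2).sum())
    ss_treatment = float(n * ((X.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_treatment
    df_t, df_e = k - 1, (n - 1) * (k - 1)
    extras = {
        "ss_total": ss_total,
        "ss_subjects": ss_subjects,
        "ss_treatment": ss_treatment,
        "ss_error": ss_error,
    }
    if ss_treatment <= 0:
        return TestResult("rm_anova", 0.0, (df_t, df_e), 1.0, (n, k), extras=extras)
    if ss_error <= 0:
        return TestResult("rm_anova", np.inf, (df_t, df_e), 0.0, (n, k),
                          degenerate=True, extras=extras)
    F = (ss_treatment / df_t) / (ss_error / df_e)
    p = float(sps.f.sf(F, df_t, df_e))
    return TestResult("rm_anova", float(F), (df_t, df_e), p, (n, k), extras=extras)


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m); m defaults to len(p)."""
    ps = list(p_values)
    if any(not (0 <= p <= 1) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    return [min(1.0, p * m) for p in ps]


def _block_ranks(X: np.ndarray) -> np.ndarray:
    return sps.rankdata(X, axis=1)  # mid-ranks for ties


def friedman_test(table) -> TestResult:
    """Friedman rank test on an (n blocks x k treatments) table.

    Tie-corrected general form: with within-block mid-ranks r_ij and rank
    sums R_j, chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum r_ij^2 -
    n k (k+1)^2 / 4); p from chi-square on k-1 df.  An all-tied table has
    statistic 0 and p 1 by convention.  Works for k >= 2.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("table must be 2-D (blocks x treatments)")
    if np.isnan(X).any():
        raise ValueError("friedman_test requires a complete table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("friedman_test needs >= 2 blocks and >= 2 treatments")
    R = _block_ranks(X)
    col_sums = R.sum(axis=0)
    S = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    D = float((R**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if D <= 0:  # every block fully tied
        return TestResult("friedman", 0.0, k - 1, 1.0, (n, k))
    stat = (k - 1) * S / D
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult("friedman", float(stat), k - 1, p, (n, k))


def conover_posthoc(table, alpha: float = 0.05) -> list[TestResult]:
    """Conover all-pairs post hoc after a Friedman test.

    Returns one TestResult per treatment pair (i, j), i < j, with the
    unadjusted two-sided p and a Bonferroni-adjusted p (m = k(k-1)/2) in
    ``extras``; ``extras['significant']`` applies alpha to the adjusted p.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or np.isnan(X).any():
        raise ValueError("conover_posthoc requires a complete 2-D table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("conover_posthoc needs >= 2 blocks and >= 2 treatments")
    R = _block_ranks(X)
    col_sums = R.sum(axis=0)
    A = float((R**2).sum())
    B = float((col_sums**2).sum()) / n
    df = (n - 1) * (k - 1)
    se2 = 2.0 * n * (A - B) / df  # 2n * MS_error of the rank layout
    pairs = list(itertools.combinations(range(k), 2))
    raw: list[TestResult] = []
    for i, j in pairs:
        diff = col_sums[i] - col_sums[j]
        if se2 <= 0:
            equal = diff == 0
            res = TestResult("conover", 0.0 if equal else np.inf, df,
                             1.0 if equal else 0.0, (n, k), degenerate=True)
        else:
            t = diff / np.sqrt(se2)
            p = float(2 * sps.t.sf(abs(t), df))
            res = TestResult("conover", float(t), df, p, (n, k))
        res.extras["pair"] = (i, j)
        raw.append(res)
    adj = bonferroni_adjust([r.p for r in raw], m=len(pairs))
    for r, pa in zip(raw, adj):
        r.extras["p_bonferroni"] = pa
        r.extras["significant"] = pa < alpha
    return raw


# ---------------------------------------------------------------------------
# The default comparison battery over pipeline outputs


def _rows_from_result(comparison: str, res: TestResult) -> dict:
    df = res.df
    if isinstance(df, tuple):
        df = f"{df[0]:g},{df[1]:g}"
    return {
        "comparison": comparison,
        "method": res.method,
        "statistic": res.statistic,
        "df": df,
        "p": res.p,
        "p_adjusted": res.extras.get("p_bonferroni", np.nan),
        "n": "/".join(str(v) for v in res.n),
        "defined": res.defined,
        "degenerate": res.degenerate,
    }


def standard_comparisons(
    lung_summaries: pd.DataFrame,
    measurements: pd.DataFrame,
    clinical: pd.DataFrame,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """The analysis' default report over a cohort's pipeline outputs.

    Comparisons: per-lung mean MPI between groups and left vs right within
    each group (Welch); FHPI of right-7 vs left-7 within group and right-7
    between groups (Welch); patient mean MPI against day-1 MAP, FiO2, RSS,
    VT and radiological grade (Pearson); VT across days 1/3/7 per group
    (RM-ANOVA, Bonferroni-adjusted pairwise paired contrasts) and FiO2
    across days (Friedman with Conover post hoc).  No adjustment is applied
    across distinct hypotheses; post hoc adjustment only within the
    repeated-measures families.
    """
    rows: list[dict] = []
    groups = sorted(patients["group"].unique())
    summ = lung_summaries.merge(
        patients[["patient_id", "group"]], left_on="image_id", right_on="patient_id"
    )

    # group comparisons of per-lung mean MPI
    if len(groups) >= 2:
        g1, g2 = groups[0], groups[1]
        for side in ("right", "left"):
            a = summ[(summ["group"] == g1) & (summ["side"] == side)]["mean_mpi"].dropna()
            b = summ[(summ["group"] == g2) & (summ["side"] == side)]["mean_mpi"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                rows.append(_rows_from_result(
                    f"mean MPI {side} lung: {g1} vs {g2}", welch_t_test(a, b)))

    # left vs right within group
    for grp in groups:
        a = summ[(summ["group"] == grp) & (summ["side"] == "left")]["mean_mpi"].dropna()
        b = summ[(summ["group"] == grp) & (summ["side"] == "right")]["mean_mpi"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            rows.append(_rows_from_result(
                f"mean MPI left vs right within {grp}", welch_t_test(a, b)))

    # 7th-space FHPI contrasts
    meas = measurements.merge(
        patients[["patient_id", "group"]], left_on="image_id", right_on="patient_id"
    )
    usable7 = meas[(meas["space"] == 7) & (~meas["excluded"])]
    for grp in groups:
        a = usable7[(usable7["group"] == grp) & (usable7["side"] == "right")]["fhpi"]
        b = usable7[(usable7["group"] == grp) & (usable7["side"] == "left")]["fhpi"]
        if len(a) >= 2 and len(b) >= 2:
            rows.append(_rows_from_result(
                f"FHPI right-7 vs left-7 within {grp}", welch_t_test(a, b)))
    if len(groups) >= 2:
        a = usable7[(usable7["group"] == groups[0]) & (usable7["side"] == "right")]["fhpi"]
        b = usable7[(usable7["group"] == groups[1]) & (usable7["side"] == "right")]["fhpi"]
        if len(a) >= 2 and len(b) >= 2:
            rows.append(_rows_from_result(
                f"FHPI right-7: {groups[0]} vs {groups[1]}", welch_t_test(a, b)))

    # correlations of patient mean MPI with day-1 covariates and grade
    patient_mpi = (
        summ.groupby("patient_id")["mean_mpi"].mean().rename("patient_mean_mpi")
    )
    day1 = clinical[clinical["day"] == 1].set_index("patient_id")
    joined = day1.join(patient_mpi, how="inner")
    for col, label in [
        ("map_cmh2o", "MAP day 1"),
        ("fio2", "FiO2 day 1"),
        ("rss", "RSS day 1"),
        ("vt_ml_kg", "VT day 1"),
        ("grade", "radiological grade"),
    ]:
        sub = joined[["patient_mean_mpi", col]].dropna()
        if len(sub) >= 3 and np.ptp(sub[col].to_numpy()) > 0:
            rows.append(_rows_from_result(
                f"mean MPI vs {label}", pearson_correlation(sub["patient_mean_mpi"], sub[col])))

    # repeated measures across days, per group
    for grp in groups:
        sub = clinical[clinical["group"] == grp]
        wide_vt = sub.pivot(index="patient_id", columns="day", values="vt_ml_kg").dropna()
        if wide_vt.shape[0] >= 2 and wide_vt.shape[1] >= 2:
            res = rm_anova(wide_vt.to_numpy())
            rows.append(_rows_from_result(f"VT across days ({grp}, RM-ANOVA)", res))
            days = list(wide_vt.columns)
            pairs = list(itertools.combinations(range(len(days)), 2))
            raws = []
            for i, j in pairs:
                tt = sps.ttest_rel(wide_vt.iloc[:, i], wide_vt.iloc[:, j])
                raws.append((i, j, float(tt.statistic), float(tt.pvalue)))
            for (i, j, t, p), pa in zip(raws, bonferroni_adjust([r[3] for r in raws])):
                res = TestResult("paired_t", t, wide_vt.shape[0] - 1, p, (wide_vt.shape[0],))
                res.extras["p_bonferroni"] = pa
                rows.append(_rows_from_result(
                    f"VT day {days[i]} vs day {days[j]} ({grp}, paired t)", res))
        wide_f = sub.pivot(index="patient_id", columns="day", values="fio2").dropna()
        if wide_f.shape[0] >= 2 and wide_f.shape[1] >= 2:
            res = friedman_test(wide_f.to_numpy())
            rows.append(_rows_from_result(f"FiO2 across days ({grp}, Friedman)", res))
            days = list(wide_f.columns)
            for ph in conover_posthoc(wide_f.to_numpy()):
                i, j = ph.extras["pair"]
                rows.append(_rows_from_result(
                    f"FiO2 day {days[i]} vs day {days[j]} ({grp}, Conover)", ph))

    return pd.DataFrame(rows)
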