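"""Statistical battery for subgroup comparisons of haemodynamic indices.

Shapiro-Wilk gates the choice between parametric (Welch t, one-way ANOVA,
mean ± sd summaries) and rank-based procedures (Mann-Whitney U,
Kruskal-Wallis, median [IQR] summaries); 2x2 categorical tables use the
Pearson chi-square, continuous covariates Pearson correlation, and
two-group effect sizes are Cohen's d with Hedges' small-sample correction.
All tests are two-tailed at a nominal alpha of 0.05, with no
multiple-testing correction across report rows (each row is a separate
nominal-level hypothesis; the report carries a caveat).

The Mann-Whitney implementation reports the U statistic of the *first*
(reference) sample together with a tie-corrected, continuity-corrected
normal-approximation Z; the sign convention is that Z > 0 means the second
(comparison) group tends to larger values.  For pooled sizes up to 12 an
exact permutation p-value is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
EXACT_MAX_N = 12


class StatError(ValueError):
    pass


@dataclass
class StatResult:
    """One test: name, statistic, two-tailed p, optional Z / exact p /
    effect size, and the per-group summaries used for reporting."""

    test: str
    statistic: float
    p: float
    z: float | None = None
    p_exact: float | None = None
    effect_size: float | None = None
    summaries: tuple = ()

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _as_array(x, name="sample") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise StatError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise StatError(f"{name} contains non-finite values")
    return arr


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p; requires 3 <= n <= 5000 and a non-degenerate
    sample."""
    arr = _as_array(x)
    if not 3 <= arr.size <= 5000:
        raise StatError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {arr.size}")
    if np.ptp(arr) == 0.0:
        raise StatError("degenerate (constant) sample")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def _is_normal(x, alpha: float = ALPHA) -> bool:
    arr = np.asarray(x, dtype=float)
    if arr.size < 3 or np.ptp(arr) == 0.0:
        return False
    if arr.size > 5000:
        arr = arr[:5000]
    return sps.shapiro(arr).pvalue > alpha


def summarize(x, normal: bool | None = None) -> str:
    """Mean ± sd for normally distributed samples, median [IQR] otherwise."""
    arr = _as_array(x)
    if normal is None:
        normal = _is_normal(arr)
    if normal:
        return f"{np.mean(arr):.3g} ± {np.std(arr, ddof=1):.3g}"
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return f"{q50:.3g} [{q25:.3g}–{q75:.3g}]"


def _exact_rank_sum_p(pooled_ranks: np.ndarray, n_x: int,
                      u_obs: float) -> float:
    """Two-sided exact permutation p for the rank-sum: enumerate every
    assignment of n_x pooled ranks, count |U - mu| >= |U_obs - mu|."""
    n = pooled_ranks.size
    mu = n_x * (n - n_x) / 2.0
    thresh = abs(u_obs - mu) - 1e-12
    offset = n_x * (n_x + 1) / 2.0
    count = 0
    for idx in combinations(range(n), n_x):
        u = pooled_ranks[list(idx)].sum() - offset
        if abs(u - mu) >= thresh:
            count += 1
    return count / comb(n, n_x)


def rank_sum_test(x, y, continuity: bool = True) -> StatResult:
    """Mann-Whitney U test (normal approximation with tie correction and,
    by default, continuity correction).

    Reports U for ``x`` (the reference group); Z > 0 means ``y`` tends to
    larger values than ``x``.  For n_x + n_y <= 12 an exact enumeration
    p-value is also computed.
    """
    ax, ay = _as_array(x, "x"), _as_array(y, "y")
    n_x, n_y = ax.size, ay.size
    pooled = np.concatenate([ax, ay])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n_x].sum()
    u_x = r_x - n_x * (n_x + 1) / 2.0
    mu = n_x * n_y / 2.0

    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise StatError("all pooled values identical")
    diff = u_x - mu
    if continuity and diff != 0.0:
        diff -= 0.5 * np.sign(diff)
    # U_x below its mean means x ranks low, i.e. y larger -> positive Z
    z = -diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    p = min(p, 1.0)

    p_exact = None
    if n <= EXACT_MAX_N:
        p_exact = _exact_rank_sum_p(ranks, n_x, u_x)
    return StatResult(test="mann_whitney_u", statistic=float(u_x), z=float(z),
                      p=float(p), p_exact=p_exact,
                      summaries=(summarize(ax), summarize(ay)))


def kruskal_wallis_test(*groups) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)):
        groups = tuple(groups[0])
    if len(groups) == 2:
        raise StatError("two groups: use rank_sum_test instead")
    if len(groups) < 3:
        raise StatError("need at least 3 groups")
    arrs = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0.0:
        raise StatError("degenerate: all values identical")
    h, p = sps.kruskal(*arrs)
    return StatResult(test="kruskal_wallis", statistic=float(h), p=float(p),
                      summaries=tuple(summarize(a) for a in arrs))


def chi_square_test(table) -> StatResult:
    """Pearson chi-square on a contingency table of counts (no Yates
    correction)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise StatError("table must be non-negative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise StatError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    return StatResult(test="chi_square", statistic=float(chi2), p=float(p))


def t_test(x, y, equal_var: bool = False) -> StatResult:
    """Two-sample t test (Welch by default), two-tailed."""
    ax, ay = _as_array(x, "x"), _as_array(y, "y")
    if ax.size < 2 or ay.size < 2:
        raise StatError("need n >= 2 per group")
    t, p = sps.ttest_ind(ax, ay, equal_var=equal_var)
    return StatResult(test="welch_t" if not equal_var else "student_t",
                      statistic=float(t), p=float(p),
                      effect_size=effect_size(ax, ay, "hedges_g"),
                      summaries=(summarize(ax, True), summarize(ay, True)))


def anova(*groups) -> StatResult:
    """One-way ANOVA F test for 3 or more groups (2 allowed for the F = t^2
    identity with the pooled-variance t)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)):
        groups = tuple(groups[0])
    arrs = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise StatError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise StatError("need n >= 2 per group")
    f, p = sps.f_oneway(*arrs)
    return StatResult(test="anova", statistic=float(f), p=float(p))


def hedges_correction(df: int) -> float:
    """Small-sample correction J = 1 - 3 / (4 df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def effect_size(x, y, kind: str = "hedges_g") -> float:
    """Cohen's d (pooled-sd standardized mean difference) or Hedges' g
    (d times the small-sample correction with df = n_x + n_y - 2)."""
    ax, ay = _as_array(x, "x"), _as_array(y, "y")
    if ax.size < 2 or ay.size < 2:
        raise StatError("need n >= 2 per group")
    n_x, n_y = ax.size, ay.size
    sp = np.sqrt(((n_x - 1) * np.var(ax, ddof=1)
                  + (n_y - 1) * np.var(ay, ddof=1)) / (n_x + n_y - 2))
    if sp == 0.0:
        raise StatError("zero pooled standard deviation")
    d = (np.mean(ax) - np.mean(ay)) / sp
    if kind == "cohen_d":
        return float(d)
    if kind == "hedges_g":
        return float(d * hedges_correction(n_x + n_y - 2))
    raise StatError(f"unknown effect size kind {kind!r}")


def correlation(x, y) -> tuple[float, float]:
    """Pearson r with its two-tailed p (t transform)."""
    ax, ay = _as_array(x, "x"), _as_array(y, "y")
    if ax.size != ay.size or ax.size < 3:
        raise StatError("need paired samples with n >= 3")
    r, p = sps.pearsonr(ax, ay)
    return float(r), float(p)


# ------------------------------------------------------- subgroup reports
#: variable -> (kind, grouping column, reference level, comparison level)
LEFT_ARTERIES = ("LAD", "Dx", "LCx", "OM", "LMS")

BINARY_VARIABLES = {
    "sex": ("sex", "male", "female"),
    "ethnicity": ("ethnicity", "white", "black_asian"),
    "smoker": ("smoker", False, True),
    "bmi_over_25": ("bmi_over_25", False, True),
    "hypertension": ("hypertension", False, True),
    "dyslipidaemia": ("dyslipidaemia", False, True),
    "diabetes": ("diabetes", False, True),
    "lung_disease": ("lung_disease", False, True),
    "valve_disease": ("valve_disease", False, True),
    "prior_mi": ("prior_mi", False, True),
    "lvsd": ("lvsd", False, True),
}
DEFAULT_VARIABLES = list(BINARY_VARIABLES)
CONTINUOUS_VARIABLES = ("age",)


def _artery_group(label: str) -> str | None:
    if label in ("LAD", "Dx"):
        return "LAD+Dx"
    if label in ("LCx", "OM"):
        return "LCx+OM"
    if label == "RCA":
        return "RCA"
    return None          # LMS: left main only, not assignable to a branch


def subgroup_report(results: pd.DataFrame, variables=None,
                    value_col: str = "cmvr_hyper_wu",
                    alpha: float = ALPHA) -> pd.DataFrame:
    """Table of subgroup comparisons of ``value_col`` (one row per
    variable).

    Binary variables use the Mann-Whitney / Welch-t pair gated on
    Shapiro-Wilk normality of both groups; ``artery`` compares the three
    branch territories (LAD+Dx vs LCx+OM vs RCA) by Kruskal-Wallis (or
    ANOVA under normality); ``artery_origin`` compares left- vs
    right-origin arteries; continuous variables use Pearson correlation.
    """
    if variables is None:
        variables = DEFAULT_VARIABLES
    if value_col not in results.columns:
        raise StatError(f"missing value column {value_col!r}")
    rows = []
    for var in variables:
        values = results[value_col].to_numpy(dtype=float)
        if var in BINARY_VARIABLES:
            col, ref, comp = BINARY_VARIABLES[var]
            if col not in results.columns:
                raise StatError(f"unknown variable {var!r}: no column "
                                f"{col!r} in results")
            mask_ref = results[col] == ref
            mask_comp = results[col] == comp
            a = values[mask_ref.to_numpy()]
            b = values[mask_comp.to_numpy()]
            if a.size == 0 or b.size == 0:
                raise StatError(
                    f"variable {var!r} has a single level in this cohort")
            normal = _is_normal(a) and _is_normal(b)
            if normal:
                res = t_test(a, b)
                stat_label = f"t = {res.statistic:.3g}"
            else:
                res = rank_sum_test(a, b)
                stat_label = f"Z = {res.z:.3g}"
            g = effect_size(a, b, "hedges_g") if min(a.size, b.size) > 1 \
                else np.nan
            rows.append({
                "variable": var,
                "group_a_summary": f"{ref}: {summarize(a, normal)} (n={a.size})",
                "group_b_summary": f"{comp}: {summarize(b, normal)} (n={b.size})",
                "test": res.test, "statistic": stat_label, "p": res.p,
                "effect_size": g, "significant": res.p < alpha})
        elif var == "artery":
            groups = {}
            for label, sub in results.groupby(
                    results["artery"].map(_artery_group)):
                groups[label] = sub[value_col].to_numpy(dtype=float)
            if len(groups) < 3:
                raise StatError("artery comparison needs all three "
                                "territories present")
            arrs = [groups[k] for k in ("LAD+Dx", "LCx+OM", "RCA")]
            normal = all(_is_normal(a) for a in arrs)
            res = anova(*arrs) if normal else kruskal_wallis_test(*arrs)
            label = "F" if normal else "H"
            rows.append({
                "variable": var,
                "group_a_summary": "; ".join(
                    f"{k}: {summarize(groups[k], normal)}"
                    for k in ("LAD+Dx", "LCx+OM", "RCA")),
                "group_b_summary": "",
                "test": res.test,
                "statistic": f"{label} = {res.statistic:.3g}",
                "p": res.p, "effect_size": np.nan,
                "significant": res.p < alpha})
        elif var == "artery_origin":
            left = values[results["artery"].isin(LEFT_ARTERIES).to_numpy()]
            right = values[(results["artery"] == "RCA").to_numpy()]
            if left.size == 0 or right.size == 0:
                raise StatError("origin comparison needs both left and "
                                "right arteries")
            normal = _is_normal(left) and _is_normal(right)
            res = t_test(left, right) if normal else rank_sum_test(left, right)
            stat_label = (f"t = {res.statistic:.3g}" if normal
                          else f"Z = {res.z:.3g}")
            rows.append({
                "variable": var,
                "group_a_summary": f"left: {summarize(left, normal)} "
                                   f"(n={left.size})",
                "group_b_summary": f"right: {summarize(right, normal)} "
                                   f"(n={right.size})",
                "test": res.test, "statistic": stat_label, "p": res.p,
                "effect_size": effect_size(left, right, "hedges_g"),
                "significant": res.p < alpha})
        elif var in CONTINUOUS_VARIABLES:
            if var not in results.columns:
                raise StatError(f"unknown variable {var!r}")
            x = results[var].to_numpy(dtype=float)
            r, p = correlation(x, values)
            rows.append({
                "variable": var,
                "group_a_summary": f"n={x.size}", "group_b_summary": "",
                "test": "pearson_r", "statistic": f"r = {r:.3g}",
                "p": p, "effect_size": r, "significant": p < alpha})
        else:
            raise StatError(f"unknown variable {var!r}")
    return pd.DataFrame(rows)


def report_to_markdown(report: pd.DataFrame) -> str:
    lines = ["| variable | group A | group B | test | statistic | p | "
             "Hedges g | significant |",
             "|---|---|---|---|---|---|---|---|"]
    for _, row in report.iterrows():
        g = "" if pd.isna(row["effect_size"]) else f"{row['effect_size']:.2f}"
        lines.append(
            f"| {row['variable']} | {row['group_a_summary']} | "
            f"{row['group_b_summary']} | {row['test']} | {row['statistic']} "
            f"| {row['p']:.4g} | {g} | {'*' if row['significant'] else ''} |")
    lines.append("")
    lines.append(f"Nominal two-tailed alpha = {ALPHA}; p-values are not "
                 "adjusted for multiple comparisons across rows.")
    return "\n".join(lines)
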