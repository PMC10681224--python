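"""Cohort statistics for squat region metrics.

Implements the study-style battery on long-format metric tables: median
split of the lower-limb muscle ratio (LLMR) into low/high groups,
boxplot outlier screening, two-way mixed ANOVA (2 conditions x 2 groups)
with partial eta squared and its noncentral-F confidence interval,
test-retest ICC across conditions, and shoulder-hip velocity
regressions.

The mixed ANOVA is computed from the classical sum-of-squares
decomposition. Because every subject contributes both conditions, the
between factor (group) and the within factor (condition) are orthogonal
even with unequal group sizes, so Type I/II/III sums of squares
coincide and the cell-mean formulas below are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "ICCResult",
    "RegressionResult",
    "assign_groups",
    "boxplot_outliers",
    "mixed_anova",
    "gg_epsilon",
    "eta_p2",
    "eta_p2_ci",
    "effect_size_label",
    "icc_test_retest",
    "icc_category",
    "velocity_regression",
    "homogeneity_checks",
    "anova_battery",
]

ETA_SMALL, ETA_MEDIUM, ETA_LARGE = 0.01, 0.06, 0.14
ICC_MODERATE, ICC_GOOD, ICC_EXCELLENT = 0.5, 0.75, 0.9


@dataclass
class AnovaResult:
    """One effect of the 2x2 mixed design."""

    effect: str  # condition | group | interaction
    F: float
    df1: float
    df2: float
    p: float  # Greenhouse-Geisser adjusted for within effects
    eta_p2: float
    eta_p2_ci90: tuple[float, float]
    size_label: str
    gg_epsilon: float | None = None  # only for within effects


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    category: str
    form: str = "ICC(3,1) two-way mixed, single, consistency"


@dataclass
class RegressionResult:
    r2_linear: float
    r2_poly: float
    pearson_r: float
    p_r: float
    n: int
    degree: int = 2
    coef_linear: tuple[float, ...] = ()
    coef_poly: tuple[float, ...] = ()


def assign_groups(llmr_pct: dict | pd.Series) -> dict:
    """Median split of LLMR percentages into "low" and "high" groups.

    The sorted lower half (``n // 2`` participants) is "low", the rest
    "high", so with an odd cohort the median participant lands in the
    high group and split sizes differ by one. Ties straddling the cut
    are resolved by participant order (deterministic) with a warning.
    """
    items = list(pd.Series(dict(llmr_pct)).items())
    if len(items) < 2:
        raise ValueError("need at least 2 participants to form groups")
    order = sorted(range(len(items)), key=lambda i: (items[i][1], i))
    n_low = len(items) // 2
    cut_lo, cut_hi = items[order[n_low - 1]][1], items[order[n_low]][1]
    if cut_lo == cut_hi:
        warnings.warn(
            "LLMR ties straddle the median cut; assignment follows participant order",
            stacklevel=2,
        )
    labels = {}
    for rank, i in enumerate(order):
        labels[items[i][0]] = "low" if rank < n_low else "high"
    return labels


def boxplot_outliers(values: np.ndarray) -> np.ndarray:
    """Tukey boxplot rule: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for the boxplot rule")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def eta_p2(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    return F * df1 / (F * df1 + df2)


def effect_size_label(value: float) -> str:
    """small (<0.06), medium (0.06-0.14), large (>0.14)."""
    if value > ETA_LARGE:
        return "large"
    if value >= ETA_MEDIUM:
        return "medium"
    return "small"


def eta_p2_ci(F: float, df1: float, df2: float, conf: float = 0.90) -> tuple[float, float]:
    """Confidence interval for partial eta squared.

    Inverts the noncentral F distribution for the noncentrality
    parameter lambda at each tail and maps to the eta_p2 scale via
    ``lambda / (lambda + df1 + df2 + 1)``. The lower bound is clipped
    at 0 (and is 0 whenever the observed F is unremarkable).
    """
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    if F < 0:
        raise ValueError("F must be non-negative")
    if F == 0:
        return (0.0, 0.0)
    alpha = 1.0 - conf
    n_scale = df1 + df2 + 1

    def solve(target: float) -> float:
        f = lambda lam: sps.ncf.cdf(F, df1, df2, lam) - target
        if f(0.0) <= 0:
            return 0.0
        hi = 1.0
        while f(hi) > 0:
            hi *= 2
            if hi > 1e7:  # pragma: no cover - pathological F
                return hi
        return optimize.brentq(f, 0.0, hi)

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    return (lam_lo / (lam_lo + n_scale), lam_hi / (lam_hi + n_scale))


def gg_epsilon(within_matrix: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from a subjects x levels matrix.

    With two within-subject levels the value is identically 1 (a single
    difference score cannot violate sphericity); the general formula is
    kept for completeness.
    """
    X = np.asarray(within_matrix, dtype=float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (row_means**2).sum() + k**2 * grand**2)
    if den == 0:
        return 1.0
    return float(min(num / den, 1.0))


def _check_design(df: pd.DataFrame, dv: str, within: str, between: str, subject: str):
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete within-subject pairs; balance the table first")
    groups = df.groupby(subject)[between].first()
    counts = groups.value_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(counts.index)}")
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 participants")
    return wide, groups


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "participant_id",
    compute_ci: bool = True,
) -> list[AnovaResult]:
    """Two-way mixed ANOVA: one between factor, one within factor.

    Returns the group (between), condition (within) and interaction
    effects with F, degrees of freedom, Greenhouse-Geisser adjusted p
    for the within effects, partial eta squared with its 90% CI and the
    size label. A zero residual (degenerate, e.g. noise-free null data)
    yields F = 0 with a warning rather than an error. ``compute_ci=False``
    skips the (comparatively expensive) noncentral-F interval, useful in
    large simulation sweeps.
    """
    wide, groups = _check_design(df, dv, within, between, subject)
    y = df[dv].to_numpy(dtype=float)
    k = wide.shape[1]
    N = wide.shape[0]
    G = 2
    gm = y.mean()

    subj_means = wide.mean(axis=1)
    ss_total = ((y - gm) ** 2).sum()
    ss_between_subj = k * ((subj_means - gm) ** 2).sum()

    gmeans = df.groupby(between)[dv].mean()
    ngs = groups.value_counts()
    ss_group = sum(k * ngs[g] * (gmeans[g] - gm) ** 2 for g in gmeans.index)
    ss_subj_within = ss_between_subj - ss_group

    cmeans = df.groupby(within)[dv].mean()
    ss_cond = sum(N * (cmeans[c] - gm) ** 2 for c in cmeans.index)
    cell = df.groupby([between, within])[dv].mean()
    ss_inter = sum(
        ngs[g] * (cell[g, c] - gmeans[g] - cmeans[c] + gm) ** 2
        for g, c in cell.index
    )
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_inter

    df_group, df_subj = G - 1, N - G
    df_cond = k - 1
    df_inter = (G - 1) * (k - 1)
    df_err = (N - G) * (k - 1)

    eps = gg_epsilon(wide.to_numpy())
    if abs(eps - 1.0) < 1e-12 and k == 2:
        logger.info(
            "Greenhouse-Geisser epsilon = 1: a 2-level within factor cannot "
            "violate sphericity; the correction is a no-op"
        )

    def ratio(ss_eff, df_eff, ss_err, df_error):
        if ss_err <= 0:
            warnings.warn("zero residual variance; F set to 0 (degenerate)", stacklevel=3)
            return 0.0
        return (ss_eff / df_eff) / (ss_err / df_error)

    def ci(F_e, df_eff, df_error):
        if not compute_ci:
            return (float("nan"), float("nan"))
        return eta_p2_ci(F_e, df_eff, df_error)

    results = []
    F_g = ratio(ss_group, df_group, ss_subj_within, df_subj)
    p_g = sps.f.sf(F_g, df_group, df_subj)
    e_g = eta_p2(F_g, df_group, df_subj)
    results.append(
        AnovaResult("group", F_g, df_group, df_subj, float(p_g), e_g,
                    ci(F_g, df_group, df_subj), effect_size_label(e_g))
    )
    for name, ss_eff, df_eff in (
        ("condition", ss_cond, df_cond),
        ("interaction", ss_inter, df_inter),
    ):
        F_e = ratio(ss_eff, df_eff, ss_err_within, df_err)
        p_e = sps.f.sf(F_e, df_eff * eps, df_err * eps)
        e_e = eta_p2(F_e, df_eff, df_err)
        results.append(
            AnovaResult(name, F_e, df_eff, df_err, float(p_e), e_e,
                        ci(F_e, df_eff, df_err), effect_size_label(e_e),
                        gg_epsilon=eps)
        )
    return results


def icc_category(icc: float) -> str:
    """poor (<0.5), moderate (0.5-0.75), good (0.75-0.9), excellent (>0.9)."""
    if icc > ICC_EXCELLENT:
        return "excellent"
    if icc >= ICC_GOOD:
        return "good"
    if icc >= ICC_MODERATE:
        return "moderate"
    return "poor"


def icc_test_retest(pairs: pd.DataFrame | np.ndarray) -> ICCResult:
    """Test-retest reliability across the two conditions.

    ``pairs`` is an ``(n, 2)`` array (or DataFrame) of per-participant
    (non-fatigue, fatigue) values. Uses the two-way mixed-effects,
    single-measurement, consistency ICC — ICC(3,1) — with its 95% CI.
    Zero variance in both ratings leaves the coefficient undefined.
    """
    import pingouin as pg

    X = np.asarray(pairs, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.allclose(X, X.flat[0]):
        return ICCResult(float("nan"), (float("nan"), float("nan")), float("nan"),
                         "undefined")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["a", "b"], n),
            "score": X.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin warns on perfect agreement
        tab = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    row = tab.loc["ICC3"] if "ICC3" in tab.index else tab.loc["ICC(C,1)"]
    icc = float(min(row["ICC"], 1.0))
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    lo, hi = (float(min(b, 1.0)) for b in row[ci_col])
    return ICCResult(icc, (lo, hi), float(row["pval"]), icc_category(icc))


def velocity_regression(
    x: np.ndarray, y: np.ndarray, degree: int = 2
) -> RegressionResult:
    """Linear and polynomial OLS fits of hip velocity on shoulder velocity.

    Both fits are ordinary least squares on the pooled per-participant
    phase-mean velocities; the polynomial (default degree 2, matching
    the single-bend curvature of the relationship) nests the linear fit,
    so ``r2_poly >= r2_linear`` always. Pearson's r comes with a
    two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")

    def r2(deg: int) -> tuple[float, tuple[float, ...]]:
        coef = np.polyfit(x, y, deg)
        resid = y - np.polyval(coef, x)
        sst = ((y - y.mean()) ** 2).sum()
        if sst == 0:
            return 1.0, tuple(coef)
        return float(1.0 - (resid**2).sum() / sst), tuple(coef)

    r2_lin, c_lin = r2(1)
    r2_pol, c_pol = r2(degree)
    r, p = sps.pearsonr(x, y)
    return RegressionResult(
        r2_linear=r2_lin, r2_poly=max(r2_pol, r2_lin), pearson_r=float(r),
        p_r=float(p), n=int(x.size), degree=degree,
        coef_linear=c_lin, coef_poly=c_pol,
    )


def homogeneity_checks(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "participant_id",
) -> dict:
    """Levene's test per condition and Box's M across condition covariances.

    Levene (center = mean) compares group variances within each
    condition; Box's M compares the 2x2 condition covariance matrices
    between groups. Reported, never used to gate the ANOVA. A singular
    covariance skips Box's M with a warning.
    """
    import pingouin as pg

    report: dict = {"levene": {}, "box_m": None}
    for cond, sub in df.groupby(within):
        samples = [g[dv].to_numpy() for _, g in sub.groupby(between)]
        stat, p = sps.levene(*samples, center="mean")
        report["levene"][cond] = {"W": float(stat), "p": float(p)}
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    wide[between] = df.groupby(subject)[between].first()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bm = pg.box_m(wide, dvs=list(wide.columns[:-1]), group=between)
        row = bm.iloc[0]
        report["box_m"] = {
            "Chi2": float(row["Chi2"]),
            "df": float(row["df"]),
            "p": float(row["pval"]),
        }
    except Exception as exc:  # singular covariance and friends
        warnings.warn(f"Box's M skipped: {exc}", stacklevel=2)
    return report


def drop_outlier_subjects(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "participant_id",
) -> tuple[pd.DataFrame, list]:
    """Exclude subjects flagged by the boxplot rule in any design cell.

    Screening is per cell (group x condition); a flagged value removes
    the participant pairwise for this variable, keeping the
    within-subject design complete.
    """
    flagged: set = set()
    for _, cell in df.groupby([between, within]):
        if len(cell) < 4:
            continue
        mask = boxplot_outliers(cell[dv].to_numpy())
        flagged.update(cell.loc[mask, subject])
    kept = df[~df[subject].isin(flagged)]
    return kept, sorted(flagged)


def anova_battery(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    screen_outliers: bool = True,
) -> pd.DataFrame:
    """Mixed ANOVA + ICC per variable of a long-format metrics table.

    ``table`` columns: participant_id, condition, group, variable,
    value (joint/region/units pass through if present). Each variable is
    analysed per joint, keyed ``<variable>_<joint>`` (bare variable name
    for joint-less quantities such as durations). Returns one row per
    variable x effect with the ANOVA quantities, the test-retest ICC,
    and the outliers excluded for that variable.
    """
    required = {"participant_id", "condition", "group", "variable", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    table = table.copy()
    if "joint" in table.columns:
        joint = table["joint"].fillna("").astype(str)
        table["variable"] = np.where(
            joint == "", table["variable"], table["variable"] + "_" + joint
        )
    out = []
    names = variables or sorted(table["variable"].unique())
    for var in names:
        sub = table[table["variable"] == var]
        if sub.empty:
            continue
        excluded: list = []
        if screen_outliers:
            sub, excluded = drop_outlier_subjects(sub)
        try:
            results = mixed_anova(sub)
        except ValueError as exc:
            warnings.warn(f"{var}: skipped ({exc})", stacklevel=2)
            continue
        wide = sub.pivot_table(index="participant_id", columns="condition",
                               values="value")
        cols = [c for c in ("nonfatigue", "fatigue") if c in wide.columns]
        icc = icc_test_retest(wide[cols].to_numpy()) if len(cols) == 2 else None
        for res in results:
            out.append(
                {
                    "variable": var,
                    "effect": res.effect,
                    "F": res.F,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                    "eta_p2": res.eta_p2,
                    "eta_p2_ci90_lo": res.eta_p2_ci90[0],
                    "eta_p2_ci90_hi": res.eta_p2_ci90[1],
                    "size_label": res.size_label,
                    "gg_epsilon": res.gg_epsilon,
                    "icc": icc.icc if icc else float("nan"),
                    "icc_ci95_lo": icc.ci95[0] if icc else float("nan"),
                    "icc_ci95_hi": icc.ci95[1] if icc else float("nan"),
                    "icc_category": icc.category if icc else "",
                    "n_excluded": len(excluded),
                    "excluded": ",".join(map(str, excluded)),
                }
            )
    return pd.DataFrame(out)
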