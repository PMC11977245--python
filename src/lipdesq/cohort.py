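"""Cohort-level analysis: method agreement and age/sex desquamation trends.

Two study designs are served. First, the method-comparison design: per
subject, a desquamation rate (image-based or tape-strip) is compared with
the final visual score via Pearson correlation and the mean squared
residual about the ordinary-least-squares line of min-max-normalized rate
on score. Second, the population design: rates over a large cohort
(default ages 20-69, both sexes) are summarized per decade
(Kruskal-Wallis plus pairwise Wilcoxon rank-sum with Holm adjustment),
smoothed with local regression, tested for monotone trend (Spearman and
OLS slope), and scanned for a change in slope at each candidate age — the
breakpoint scan that localizes, e.g., the female peak in the late 30s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIDE_N = 30
DEFAULT_SPAN = 0.75


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodComparison:
    """Agreement of one rate method with the visual-score ground truth."""

    r: float
    p: float
    mse: float
    slope: float
    intercept: float
    n: int
    normalization: str = "minmax"

    def summary(self) -> str:
        return (
            f"n = {self.n}: r = {self.r:.3f} (p = {self.p:.3g}), "
            f"MSE about OLS line = {self.mse:.3f} "
            f"[rate normalization: {self.normalization}]"
        )


def normalize_rates(rates) -> np.ndarray:
    """Min-max scale rates to [0, 1]; constant input is an error."""
    arr = np.asarray(rates, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least two rates to normalize")
    rng = np.ptp(arr)
    if rng == 0:
        raise ValueError("cannot min-max normalize constant rates")
    return (arr - arr.min()) / rng


def compare_to_va(rates, va_final, normalize: bool = True) -> MethodComparison:
    """Pearson r/p of rate vs final VA score and MSE about the OLS line.

    The OLS line regresses the (optionally min-max normalized) rate on the
    VA score; MSE is the mean squared vertical residual, i.e. how tightly
    measured values concentrate around the regression line.
    """
    x = np.asarray(va_final, dtype=np.float64)
    y = np.asarray(rates, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("rates and VA scores must be paired")
    if x.size < 3:
        raise ValueError("need at least three subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in rates or VA scores")
    if normalize:
        y = normalize_rates(y)
    r, p = stats.pearsonr(y, x)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    mse = float(np.mean(fit.resid ** 2))
    return MethodComparison(
        r=float(r), p=float(p), mse=mse,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        n=int(x.size),
        normalization="minmax" if normalize else "none",
    )


# ---------------------------------------------------------------------------
# cohort records and per-decade summaries
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame, age_range=(20, 69)) -> pd.DataFrame:
    """Check a cohort table (subject_id, age, sex, rate) and coerce dtypes."""
    required = {"age", "sex", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    out = df.copy()
    out["age"] = out["age"].astype(int)
    out["rate"] = out["rate"].astype(float)
    if (out["rate"] < 0).any():
        raise ValueError("rates must be >= 0")
    lo, hi = age_range
    bad = out[(out["age"] < lo) | (out["age"] > hi)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} records outside the configured age range {lo}-{hi}"
        )
    sexes = set(out["sex"].unique())
    if not sexes <= {"male", "female"}:
        raise ValueError(f"unrecognized sex labels: {sorted(sexes - {'male', 'female'})}")
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Per-decade means with omnibus and pairwise nonparametric tests."""

    table: pd.DataFrame            # decade, n, mean_rate, median_rate
    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame         # group_a, group_b, p_raw, p_holm


def _decade_label(age: int) -> str:
    return f"{(age // 10) * 10}s"


def group_summary(df: pd.DataFrame, sex: str | None = None) -> GroupSummary:
    """Decade-group comparison of rates (Kruskal-Wallis + pairwise rank-sum).

    Pairwise tests are two-sided Wilcoxon rank-sum (Mann-Whitney); Holm-
    adjusted p-values are reported alongside the unadjusted ones. Groups
    with fewer than 2 members are excluded with a warning.
    """
    data = df if sex is None else df[df["sex"] == sex]
    if data.empty:
        raise ValueError("no records to summarize")
    data = data.assign(decade=data["age"].map(_decade_label))
    groups = {}
    for name, g in data.groupby("decade"):
        if len(g) < 2:
            warnings.warn(f"decade group {name} has < 2 members; excluded")
            continue
        groups[name] = g["rate"].to_numpy()
    if len(groups) < 2:
        raise ValueError("need at least two decade groups with >= 2 members")
    names = sorted(groups)
    kw_stat, kw_p = stats.kruskal(*[groups[n] for n in names])
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "p_raw": float(res.pvalue)})
    pw = pd.DataFrame(rows)
    pw["p_holm"] = multipletests(pw["p_raw"], method="holm")[1]
    table = pd.DataFrame(
        {
            "decade": names,
            "n": [len(groups[n]) for n in names],
            "mean_rate": [float(groups[n].mean()) for n in names],
            "median_rate": [float(np.median(groups[n])) for n in names],
        }
    )
    return GroupSummary(table=table, kruskal_stat=float(kw_stat),
                        kruskal_p=float(kw_p), pairwise=pw)


# ---------------------------------------------------------------------------
# trend tests, local regression, breakpoint scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendTests:
    """Monotone-trend statistics of rate vs age for one sex (or pooled)."""

    n: int
    spearman_rho: float
    spearman_p: float
    slope: float
    slope_p: float
    intercept: float
    pearson_r: float
    pearson_p: float
    shapiro_p_rate: float


def trend_tests(df: pd.DataFrame, sex: str | None = None) -> TrendTests:
    """Spearman correlation and OLS slope of rate on age.

    Normality of the rates is assessed with Shapiro-Wilk and logged; both
    Pearson and Spearman are always reported (no automatic switching), the
    nonparametric Spearman being the primary trend statistic.
    """
    data = df if sex is None else df[df["sex"] == sex]
    if len(data) < 10:
        raise ValueError("need at least 10 records for trend tests")
    age = data["age"].to_numpy(dtype=float)
    rate = data["rate"].to_numpy(dtype=float)
    sw_p = (float(stats.shapiro(rate).pvalue)
            if np.ptp(rate) > 0 and len(rate) <= 5000 else float("nan"))
    logger.info("Shapiro-Wilk p for rates (%s): %.4g", sex or "all", sw_p)
    if np.ptp(rate) == 0:
        rho, rho_p = float("nan"), float("nan")
        pr, pr_p = float("nan"), float("nan")
    else:
        rho, rho_p = stats.spearmanr(age, rate)
        pr, pr_p = stats.pearsonr(age, rate)
    lr = stats.linregress(age, rate)
    return TrendTests(
        n=len(data),
        spearman_rho=float(rho), spearman_p=float(rho_p),
        slope=float(lr.slope), slope_p=float(lr.pvalue),
        intercept=float(lr.intercept),
        pearson_r=float(pr), pearson_p=float(pr_p),
        shapiro_p_rate=sw_p,
    )


def local_trend(df: pd.DataFrame, sex: str | None = None,
                span: float = DEFAULT_SPAN) -> pd.DataFrame:
    """Locally weighted regression (lowess) of rate on age.

    Returns a DataFrame (age, fitted) evaluated at the observed ages.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    data = df if sex is None else df[df["sex"] == sex]
    if len(data) < 20:
        raise ValueError("need at least 20 records for local regression")
    age = data["age"].to_numpy(dtype=float)
    rate = data["rate"].to_numpy(dtype=float)
    xs = np.unique(age)
    fitted = sm.nonparametric.lowess(rate, age, frac=span, xvals=xs)
    return pd.DataFrame({"age": xs, "fitted": fitted})


@dataclass(frozen=True)
class InflectionResult:
    """Outcome of the slope-difference breakpoint scan.

    ``p_by_age`` maps each candidate age to the slope-change p-value;
    ``breakpoint_age`` is the candidate with the smallest p (ties broken
    toward the younger age). ``p_adjusted`` Bonferroni-corrects the minimum
    p for the number of candidates scanned, and ``significant`` flags it at
    the configured level.
    """

    breakpoint_age: int
    slope_before: float
    slope_after: float
    p_by_age: dict[int, float]
    p_min: float
    p_adjusted: float
    n_candidates: int
    significant: bool
    method: str = "interaction"
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            "Breakpoint scan (slope-difference test at each candidate age)",
            f"  method: {self.method}; candidates scanned: {self.n_candidates}",
            f"  breakpoint age: {self.breakpoint_age}",
            f"  slope before: {self.slope_before:+.4f} %/yr; "
            f"slope after: {self.slope_after:+.4f} %/yr",
            f"  min p = {self.p_min:.3g}; Bonferroni-adjusted p = {self.p_adjusted:.3g}"
            f" -> {'significant' if self.significant else 'not significant'}"
            f" at alpha = {self.alpha}",
        ]
        return "\n".join(lines)


def _segment_slopes(age: np.ndarray, rate: np.ndarray, a: int) -> tuple[float, float]:
    left = age <= a
    sl = stats.linregress(age[left], rate[left]).slope
    sr = stats.linregress(age[~left], rate[~left]).slope
    return float(sl), float(sr)


def find_inflection(
    df: pd.DataFrame,
    sex: str | None = None,
    min_side_n: int = DEFAULT_MIN_SIDE_N,
    method: str = "interaction",
    alpha: float = 0.05,
) -> InflectionResult:
    """Scan candidate ages for the largest change in the rate-vs-age slope.

    At each candidate age ``a`` (every age leaving at least ``min_side_n``
    records on both sides), the slope difference between the segments
    age <= a and age > a is tested:

    - ``method="interaction"`` (default): a single piecewise-linear model
      ``rate ~ age + max(age - a, 0)`` is fitted by OLS and the hinge
      (slope-change) coefficient's t-test p-value is taken.
    - ``method="two_fit"``: two independent OLS lines are fitted and the
      slope difference z-tested using their standard errors.

    The reported before/after slopes always come from the two separate
    segment fits at the selected age. Because ~dozens of correlated tests
    are scanned, the minimum p is Bonferroni-adjusted by the number of
    candidates before the significance call.
    """
    if method not in ("interaction", "two_fit"):
        raise ValueError(f"unknown method {method!r}")
    data = df if sex is None else df[df["sex"] == sex]
    age = data["age"].to_numpy(dtype=float)
    rate = data["rate"].to_numpy(dtype=float)
    ages = np.unique(age.astype(int))
    candidates = [
        int(a) for a in ages
        if (age <= a).sum() >= min_side_n and (age > a).sum() >= min_side_n
    ]
    if not candidates:
        raise ValueError(
            f"no candidate age leaves >= {min_side_n} records on both sides"
        )
    p_by_age: dict[int, float] = {}
    for a in candidates:
        if method == "interaction":
            hinge = np.maximum(age - a, 0.0)
            X = sm.add_constant(np.column_stack([age, hinge]))
            fit = sm.OLS(rate, X).fit()
            p_by_age[a] = float(fit.pvalues[2])
        else:
            left = age <= a
            fl = stats.linregress(age[left], rate[left])
            fr = stats.linregress(age[~left], rate[~left])
            se = np.hypot(fl.stderr, fr.stderr)
            z = (fl.slope - fr.slope) / se if se > 0 else 0.0
            p_by_age[a] = float(2 * stats.norm.sf(abs(z)))
    # argmin p, ties toward the younger age (dict preserves ascending order)
    bp = min(p_by_age, key=lambda a: (p_by_age[a], a))
    p_min = p_by_age[bp]
    p_adj = min(1.0, p_min * len(candidates))
    slope_before, slope_after = _segment_slopes(age, rate, bp)
    return InflectionResult(
        breakpoint_age=bp,
        slope_before=slope_before,
        slope_after=slope_after,
        p_by_age=p_by_age,
        p_min=p_min,
        p_adjusted=p_adj,
        n_candidates=len(candidates),
        significant=bool(p_adj < alpha),
        method=method,
        alpha=alpha,
    )
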