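"""Statistical ledger for paired stiffness-change analysis.

Covers: paired relative changes, Tukey and ROUT (Q = 1%) outlier screens plus
a robust pre/post relationship screen, Box-Cox transform selection, a mixed
model with treatment and compression-force level as fixed effects and
measurement location as random intercept, Bonferroni adjustment, one-sample
t-tests of relative changes against the 100% baseline, Mann-Whitney tests,
and distribution-free median confidence intervals — the full inference chain
the paired pre/post designs run through.

Ordinary tests (t, Mann-Whitney, Shapiro-Wilk) and the mixed-model numerics
delegate to scipy/statsmodels; the screens and the order-statistic median CI
are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "OutlierReport",
    "EffectTestResult",
    "MedianCI",
    "paired_changes",
    "tukey_outliers",
    "rout_outliers",
    "relationship_screen",
    "boxcox_select",
    "fit_lme",
    "one_sample_vs_baseline",
    "median_ci",
    "mann_whitney",
    "bonferroni",
]


@dataclass(frozen=True)
class OutlierReport:
    """Result of one outlier screen: flagged vs retained ids (disjoint,
    jointly exhaustive)."""

    method: str
    parameters: dict
    flagged_ids: list
    retained_ids: list

    def __post_init__(self) -> None:
        if set(self.flagged_ids) & set(self.retained_ids):
            raise ValueError("flagged and retained ids overlap")


class MedianCI(NamedTuple):
    median: float
    ci_low: float
    ci_high: float
    method: str


@dataclass(frozen=True)
class EffectTestResult:
    """Fixed-effect estimates and (adjusted) p-values of a mixed-model fit."""

    fixed_effects: list  # of dicts: term, estimate, p_value, adjusted_p
    transform_lambda: float | None
    n: int
    N: int
    converged: bool = True
    shapiro_p: float | None = None
    diagnostics: dict = field(default_factory=dict)


def paired_changes(pre, post) -> pd.DataFrame:
    """Paired relative stiffness changes per location.

    ``pre`` and ``post`` are mappings or Series of Young's modulus (Pa)
    indexed by location id. Returns a DataFrame with ``rel_change`` =
    post/pre x 100 (the treatment-effect view) and ``rel_to_pre_median`` =
    post / median(pre cohort) x 100 (the variability view).
    """
    pre = pd.Series(pre, dtype=float)
    post = pd.Series(post, dtype=float)
    unmatched = set(pre.index) ^ set(post.index)
    if unmatched:
        raise ValueError(f"unmatched location ids: {sorted(unmatched)}")
    pre = pre.sort_index()
    post = post.reindex(pre.index)
    return pd.DataFrame(
        {
            "location_id": pre.index,
            "E_pre_Pa": pre.to_numpy(),
            "E_post_Pa": post.to_numpy(),
            "rel_change": (post / pre * 100.0).to_numpy(),
            "rel_to_pre_median": (post / pre.median() * 100.0).to_numpy(),
        }
    ).reset_index(drop=True)


def _ids_or_default(values: Sequence[float], ids) -> list:
    if ids is None:
        return list(range(len(values)))
    ids = list(ids)
    if len(ids) != len(values):
        raise ValueError("ids and values length mismatch")
    return ids


def tukey_outliers(values: Sequence[float], k: float = 1.5, ids=None) -> OutlierReport:
    """Tukey's fences: flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation of order statistics (numpy's default
    percentile convention); the convention is fixed here because published
    quartile definitions differ.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("Tukey screen needs >= 4 values")
    ids = _ids_or_default(x, ids)
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = (x < lo) | (x > hi)
    return OutlierReport(
        method="tukey",
        parameters={"k": k, "fence_low": float(lo), "fence_high": float(hi)},
        flagged_ids=[i for i, o in zip(ids, out) if o],
        retained_ids=[i for i, o in zip(ids, out) if not o],
    )


def rout_outliers(values: Sequence[float], Q: float = 0.01, ids=None) -> OutlierReport:
    """ROUT-style robust outlier detection for a pooled (constant-model) sample.

    Residuals are taken from the median; the robust scale is the RSDR — the
    68.27th percentile of absolute residuals with the small-sample correction
    n/(n - K), K = 1. Per-point t-like statistics |r_i|/RSDR get two-sided
    p-values on n - K df and are tested from the most extreme inward with the
    sequential false-discovery rule p_(i) < Q * (n - i + 1) / n; scanning
    stops at the first failure.

    A sample whose residuals are all zero has no scale and raises
    "degenerate sample"; if the scale collapses to zero while some points lie
    off the median, exactly those points are flagged (they sit infinitely
    many robust SDs out).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("ROUT screen needs >= 10 values")
    if not 0 < Q < 1:
        raise ValueError("Q must be in (0, 1)")
    ids = _ids_or_default(x, ids)
    K = 1
    resid = x - np.median(x)
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / (n - K)
    if rsdr == 0.0:
        if np.all(resid == 0):
            raise ValueError("degenerate sample: zero robust scale")
        out = resid != 0
        return OutlierReport(
            method="rout",
            parameters={"Q": Q, "rsdr": 0.0},
            flagged_ids=[i for i, o in zip(ids, out) if o],
            retained_ids=[i for i, o in zip(ids, out) if not o],
        )
    t = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - K)
    order = np.argsort(p)  # most extreme first
    n_flag = 0
    for i, j in enumerate(order):
        if p[j] < Q * (n - i) / n:
            n_flag = i + 1
        else:
            break
    flagged = set(order[:n_flag].tolist())
    return OutlierReport(
        method="rout",
        parameters={"Q": Q, "rsdr": rsdr},
        flagged_ids=[ids[j] for j in sorted(flagged)],
        retained_ids=[ids[j] for j in range(n) if j not in flagged],
    )


def _robust_z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized robust residuals of a Siegel repeated-median line fit."""
    slope, intercept = sps.siegelslopes(y, x)
    r = y - (intercept + slope * x)
    scale = 1.4826 * np.median(np.abs(r - np.median(r)))
    if scale == 0:
        # exact relationship: any point off the line is infinitely far out
        return np.where(r == 0, 0.0, np.inf)
    return r / scale


def relationship_screen(
    pairs: Sequence[tuple], residual_threshold: float = 3.5, ids=None
) -> OutlierReport:
    """Flag pre/post pairs lacking both a linear and a logarithmic
    relationship with the rest of the cohort.

    Robust (repeated-median) lines of post on pre are fitted in linear and in
    log-log space; a pair is flagged only when its standardized robust
    residual exceeds ``residual_threshold`` under BOTH models. Pairs with
    non-positive values cannot enter the log model (a warning is emitted) and
    are then judged on the linear model alone.
    """
    pairs = list(pairs)
    if len(pairs) < 8:
        raise ValueError("relationship screen needs >= 8 pairs")
    ids = _ids_or_default(pairs, ids)
    pre = np.array([p[0] for p in pairs], dtype=float)
    post = np.array([p[1] for p in pairs], dtype=float)

    z_lin = np.abs(_robust_z(pre, post))
    pos = (pre > 0) & (post > 0)
    z_log = np.full(len(pairs), np.nan)
    if (~pos).any():
        warnings.warn(
            f"{int((~pos).sum())} pair(s) with non-positive values excluded "
            "from the log model",
            stacklevel=2,
        )
    if pos.sum() >= 3:
        z_log[pos] = np.abs(_robust_z(np.log(pre[pos]), np.log(post[pos])))

    out = np.zeros(len(pairs), dtype=bool)
    for i in range(len(pairs)):
        if np.isnan(z_log[i]):
            out[i] = z_lin[i] > residual_threshold
        else:
            out[i] = (z_lin[i] > residual_threshold) and (z_log[i] > residual_threshold)
    return OutlierReport(
        method="relationship",
        parameters={"residual_threshold": residual_threshold},
        flagged_ids=[i for i, o in zip(ids, out) if o],
        retained_ids=[i for i, o in zip(ids, out) if not o],
    )


def boxcox_select(
    values: Sequence[float], grid: tuple = (-2.0, 2.0, 0.01)
) -> tuple[float, np.ndarray]:
    """Pick the Box-Cox lambda maximizing the profile log-likelihood on a
    fixed grid (default [-2, 2], step 0.01; lambda = 0 is the log transform).

    Returns ``(lambda, transformed_values)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.all(x == x[0]):
        raise ValueError("lambda undefined for a constant sample")
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    # profile log-likelihood (lam - 1) * sum(log x) - n/2 * log(MLE variance
    # of the transformed sample), vectorized over the whole grid
    logx = np.log(x)
    n = x.size
    with np.errstate(over="ignore", invalid="ignore"):
        lg = lambdas[:, None]
        y = np.where(np.abs(lg) > 1e-12, (np.exp(lg * logx[None, :]) - 1) / lg, logx[None, :])
        var = y.var(axis=1)
    llf = (lambdas - 1.0) * logx.sum() - 0.5 * n * np.log(var)
    llf[~np.isfinite(llf)] = -np.inf
    lam = float(lambdas[int(np.argmax(llf))])
    transformed = sps.boxcox(x, lmbda=lam)
    return lam, np.asarray(transformed)


def fit_lme(
    table: pd.DataFrame,
    response: str = "E_Pa",
    treatment_col: str = "treatment",
    force_col: str | None = "force_level",
    location_col: str = "location_id",
    *,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    transform: str = "auto",
) -> EffectTestResult:
    """Mixed-effects ANOVA for the paired stiffness design.

    Fits ``response ~ treatment (+ force_level)`` with a random intercept per
    measurement location. Under ``transform="auto"`` the response is first
    Box-Cox transformed when a Shapiro-Wilk test rejects normality at
    ``alpha`` (the automated stand-in for quantile-quantile inspection);
    ``"none"`` and ``"boxcox"`` force the respective behavior. Fixed-effect
    p-values use the Wald statistic referred to a t distribution with
    ``n_paired_locations - 1`` degrees of freedom (the containment df of a
    within-location effect; the asymptotic normal reference is
    anti-conservative at these cohort sizes), then get a Bonferroni
    adjustment over the tested terms (``bonferroni_m`` overrides the count).

    Raises
    ------
    ValueError
        If fewer than 2 locations carry both treatment phases. A singular or
        non-converged fit is *reported* (``converged=False`` plus
        diagnostics), not silently accepted.
    """
    df = table.copy()
    needed = {response, treatment_col, location_col}
    if force_col is not None and force_col in df.columns and df[force_col].nunique() > 1:
        needed.add(force_col)
        use_force = True
    else:
        use_force = False
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")

    both = df.groupby(location_col)[treatment_col].nunique()
    n_paired = int((both >= 2).sum())
    if n_paired < 2:
        raise ValueError(
            f"need >= 2 locations observed in both phases, got {n_paired}"
        )

    y = df[response].to_numpy(dtype=float)
    shapiro_p = float(sps.shapiro(y).pvalue) if 3 <= len(y) <= 5000 else None
    lam = None
    if transform == "boxcox" or (
        transform == "auto" and shapiro_p is not None and shapiro_p < alpha
    ):
        if np.all(y > 0):
            lam, ty = boxcox_select(y)
            df = df.assign(**{response: ty})
        else:
            lam = None  # non-positive responses: transform not applicable

    terms = [f"C({treatment_col})"]
    if use_force:
        terms.append(f"C({force_col})")
    formula = f"{response} ~ " + " + ".join(terms)
    diagnostics: dict = {}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df[location_col])
        fit = model.fit(reml=True, method="lbfgs")
    converged = bool(getattr(fit, "converged", True))
    messages = [str(w.message) for w in wlist]
    if messages:
        diagnostics["warnings"] = messages
    if any("singular" in m.lower() for m in messages):
        diagnostics["singular"] = True

    fixed = []
    tested = [t for t in fit.params.index if t not in ("Intercept", "Group Var")]
    m = bonferroni_m if bonferroni_m is not None else max(1, len(tested))
    df_t = n_paired - 1
    for term in tested:
        tval = float(fit.params[term] / fit.bse[term])
        p = float(2.0 * sps.t.sf(abs(tval), df_t))
        fixed.append(
            {
                "term": term,
                "estimate": float(fit.params[term]),
                "t": tval,
                "df": df_t,
                "p_value": p,
                "adjusted_p": bonferroni(p, m),
            }
        )
    return EffectTestResult(
        fixed_effects=fixed,
        transform_lambda=lam,
        n=len(df),
        N=df[location_col].nunique(),
        converged=converged,
        shapiro_p=shapiro_p,
        diagnostics=diagnostics,
    )


def one_sample_vs_baseline(rel_changes: Sequence[float], baseline: float = 100.0):
    """One-sample t-test of relative changes (post/pre x 100) against the
    baseline. Returns ``(t, p)``.

    An all-at-baseline sample is the exact null: t = 0, p = 1. Any other
    zero-variance sample is degenerate and raises.
    """
    x = np.asarray(rel_changes, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values")
    if np.ptp(x) == 0:
        if x[0] == baseline:
            return 0.0, 1.0
        raise ValueError("zero variance away from baseline: t undefined")
    res = sps.ttest_1samp(x, popmean=baseline)
    return float(res.statistic), float(res.pvalue)


def median_ci(values: Sequence[float], level: float = 0.95, *, seed: int = 0) -> MedianCI:
    """Median with a distribution-free confidence interval.

    For n >= 6 the interval is the classical order-statistic (sign-test)
    interval: the largest symmetric pair (x_(l), x_(n+1-l)) whose binomial
    coverage is at least ``level``. For 1 <= n < 6 no such interval with the
    nominal coverage exists, so a percentile bootstrap (2000 resamples,
    seeded) is used and recorded as the method.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    med = float(np.median(x))
    if n >= 6:
        # largest l with P(Binom(n, 1/2) <= l-1) <= (1-level)/2
        alpha = 1.0 - level
        l = int(sps.binom.ppf(alpha / 2, n, 0.5))
        # ppf returns the smallest k with cdf >= alpha/2; step down if needed
        while l > 0 and sps.binom.cdf(l - 1, n, 0.5) > alpha / 2:
            l -= 1
        l = max(l, 0)
        lo = x[max(l - 1, 0)] if l >= 1 else x[0]
        hi = x[n - l] if l >= 1 else x[-1]
        return MedianCI(med, float(lo), float(hi), "order_statistic")
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(x, size=(2000, n), replace=True), axis=1)
    lo, hi = np.percentile(boots, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return MedianCI(med, float(lo), float(hi), "bootstrap")


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact p for small tie-free samples,
    normal approximation otherwise. Returns ``(U, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p)."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("need p in [0, 1] and m >= 1")
    return min(1.0, m * p)
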