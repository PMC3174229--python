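"""Temporal dynamics of introductions per pathway.

Three layers of machinery:

* cumulative first-record curves (optionally square-root transformed to
  stabilise variance), evaluated on every calendar year in range;
* trend fitting — sequential polynomial regression (adding powers until the
  added term stops being significant) and local-linear tricube LOESS whose
  span is chosen by ANOVA-style deletion tests against a small-span start
  fit, with model complexity measured as the equivalent number of parameters
  (ENP), the trace of the smoother matrix;
* inclusion curves — the cumulative proportion of a pathway's species
  recorded by each year is modelled as a logistic function of time,
  logit F(t) = a + b t, and the time to 50% inclusion t50 = -a/b is reported
  with a 95% confidence interval from Fieller's theorem for a ratio of two
  asymptotically normal estimates.

For the inclusion fit the default likelihood treats the yearly *increments*
of the curve as an interval-censored sample from the logistic law,
conditioned on falling inside the observed record window (a type of survival
analysis on first-record times); this respects the fact that a cumulative
curve's points are not independent observations.  The classical pseudo-
likelihood that scores each year's cumulative count as an independent
binomial draw is available as ``likelihood="cumulative"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm

from .core_data import FloraTable

__all__ = [
    "CumulativeCurve",
    "SmoothFit",
    "FiellerEstimate",
    "build_cumulative",
    "fit_sequential_polynomial",
    "fit_loess_with_span_selection",
    "loess_fit",
    "deletion_test",
    "fit_inclusion_glm",
    "compare_inclusion",
]


@dataclass
class CumulativeCurve:
    pathway: str
    years: np.ndarray          # every calendar year from first to last record
    cumulative: np.ndarray     # non-decreasing counts (or their square roots)
    transform: str = "none"    # "none" | "sqrt"
    n_undated: int = 0         # species excluded for missing first-record year

    @property
    def n_species(self) -> int:
        last = self.cumulative[-1]
        return int(round(last**2 if self.transform == "sqrt" else last))


@dataclass
class SmoothFit:
    kind: str                  # "polynomial" | "loess"
    degree: int | None
    span: float | None
    enp: float
    r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    deletion_test: tuple | None = None   # (F, df_num, df_den, p)


@dataclass
class FiellerEstimate:
    pathway: str
    t50: float
    ci_low: float
    ci_high: float
    glm_coefficients: tuple    # (a, b) on the link scale
    vcov: np.ndarray
    link: str = "logit"
    g: float = float("nan")    # Fieller g-condition statistic z^2 var(b)/b^2
    g_condition_ok: bool = True

    def overlaps(self, other: "FiellerEstimate") -> bool:
        return not (self.ci_high < other.ci_low or other.ci_high < self.ci_low)


# --------------------------------------------------------------------------
# cumulative curves


def build_cumulative(
    table: FloraTable, pathway: str, transform: str = "none"
) -> CumulativeCurve:
    """Cumulative number of the pathway's species recorded by each year.

    One point per calendar year from the first to the last record; species
    without a first-record year are excluded and counted in ``n_undated``.
    """
    years = sorted(
        r.first_record_year
        for r in table
        if pathway in r.pathways and r.first_record_year is not None
    )
    n_undated = sum(
        1 for r in table if pathway in r.pathways and r.first_record_year is None
    )
    if len(years) < 2:
        raise ValueError(
            f"pathway {pathway!r} has only {len(years)} dated species; need >= 2"
        )
    grid = np.arange(years[0], years[-1] + 1)
    cum = np.searchsorted(years, grid, side="right").astype(float)
    if transform == "sqrt":
        cum = np.sqrt(cum)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return CumulativeCurve(
        pathway=pathway, years=grid, cumulative=cum, transform=transform, n_undated=n_undated
    )


# --------------------------------------------------------------------------
# polynomial trend


def fit_sequential_polynomial(curve: CumulativeCurve, alpha: float = 0.05) -> SmoothFit:
    """Raise the polynomial degree until the added power is non-significant.

    Years are centred and scaled before powering; the degree is capped at
    min(6, n - 2).  The test for each added power is the partial F test on
    the reduction in residual sum of squares.
    """
    y = np.asarray(curve.cumulative, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 points for sequential polynomial fitting")
    x = np.asarray(curve.years, dtype=float)
    xs = (x - x.mean()) / x.std()
    cap = min(6, n - 2)
    prev_rss, prev_p = _poly_rss(xs, y, 1)
    degree = 1
    fitted = prev_p
    for d in range(2, cap + 1):
        rss, pred = _poly_rss(xs, y, d)
        df_den = n - (d + 1)
        if df_den <= 0 or rss <= 0:
            break
        f = (prev_rss - rss) / (rss / df_den)
        p = stats.f.sf(f, 1, df_den)
        if p >= alpha:
            break
        degree, prev_rss, fitted = d, rss, pred
    tss = float(np.sum((y - y.mean()) ** 2))
    return SmoothFit(
        kind="polynomial",
        degree=degree,
        span=None,
        enp=float(degree + 1),
        r2=1.0 - prev_rss / tss if tss > 0 else 1.0,
        fitted=fitted,
        residuals=y - fitted,
    )


def _poly_rss(xs: np.ndarray, y: np.ndarray, degree: int) -> tuple[float, np.ndarray]:
    design = np.vander(xs, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    return float(np.sum((y - pred) ** 2)), pred


# --------------------------------------------------------------------------
# LOESS


def _loess_smoother_matrix(x: np.ndarray, span: float) -> np.ndarray:
    """Hat matrix of a local-linear tricube LOESS.

    ``span`` is the neighbourhood fraction; span >= 1 degenerates to global
    (unweighted) linear regression, so that a full-span LOESS is exactly the
    least-squares line.
    """
    n = len(x)
    L = np.empty((n, n))
    if span >= 1.0:
        X = np.column_stack([np.ones(n), x])
        return X @ np.linalg.solve(X.T @ X, X.T)
    q = max(3, int(np.ceil(span * n)))
    for i in range(n):
        d = np.abs(x - x[i])
        dmax = np.partition(d, q - 1)[q - 1]
        if dmax <= 0:
            raise ValueError(f"span {span} too small: duplicate design points dominate")
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        active = w > 0
        if active.sum() < 2:
            raise ValueError(
                f"span {span} leaves fewer than 2 points with positive weight; "
                f"minimum feasible span is about {3 / n:.3f}"
            )
        xa = x[active]
        wa = w[active]
        X = np.column_stack([np.ones(active.sum()), xa - x[i]])
        XtW = X.T * wa
        try:
            beta_row = np.linalg.solve(XtW @ X, XtW)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular local fit at span {span}; increase span beyond {q / n:.3f}"
            ) from exc
        row = np.zeros(n)
        row[active] = beta_row[0]
        L[i] = row
    return L


def loess_fit(curve: CumulativeCurve, span: float) -> SmoothFit:
    """Local-linear tricube LOESS fit at a fixed span."""
    x = np.asarray(curve.years, dtype=float)
    y = np.asarray(curve.cumulative, dtype=float)
    L = _loess_smoother_matrix(x, span)
    fitted = L @ y
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return SmoothFit(
        kind="loess",
        degree=1,
        span=span,
        enp=float(np.trace(L)),
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        fitted=fitted,
        residuals=y - fitted,
    )


def deletion_test(simple: SmoothFit, complex_: SmoothFit) -> tuple:
    """Approximate F deletion test between a simpler and a more complex fit.

    F = ((RSS_s - RSS_c) / (enp_c - enp_s)) / (RSS_c / (n - enp_c)), with
    possibly fractional degrees of freedom from the ENP difference.  For
    LOESS fits this is the usual analysis-of-variance approximation, not an
    exact finite-sample test.
    """
    rss_s = float(np.sum(simple.residuals**2))
    rss_c = float(np.sum(complex_.residuals**2))
    n = len(complex_.residuals)
    df_num = complex_.enp - simple.enp
    df_den = n - complex_.enp
    if df_num <= 0 or df_den <= 0 or rss_c <= 0:
        return (float("nan"), df_num, df_den, float("nan"))
    f = max(0.0, (rss_s - rss_c) / df_num) / (rss_c / df_den)
    return (f, df_num, df_den, float(stats.f.sf(f, df_num, df_den)))


def fit_loess_with_span_selection(
    curve: CumulativeCurve,
    start_span: float = 0.08,
    step: float = 0.01,
    alpha: float = 0.05,
) -> SmoothFit:
    """Scan spans upward from a small start value; keep the largest span whose
    deletion test against the start-span fit stays non-significant.

    The start fit is deliberately under-smoothed; increasing the span reduces
    the ENP until the smoother first differs significantly (P < alpha) from
    the start fit, and the previous (slightly smaller) span is selected.
    """
    if not 0 < start_span < 1:
        raise ValueError("start_span must lie in (0, 1)")
    if len(curve.years) < 10:
        raise ValueError("need at least 10 points for span selection")
    base = loess_fit(curve, start_span)
    chosen = base
    span = start_span + step
    while span <= 1.0 + 1e-9:
        candidate = loess_fit(curve, min(span, 1.0))
        test = deletion_test(candidate, base)
        if np.isfinite(test[3]) and test[3] < alpha:
            break
        candidate.deletion_test = test
        chosen = candidate
        span += step
    return chosen


# --------------------------------------------------------------------------
# inclusion curves and Fieller's theorem


def _interval_loglik(params: np.ndarray, edges: np.ndarray, counts: np.ndarray) -> float:
    """Log-likelihood of yearly record counts as an interval-censored logistic
    sample truncated to the observed window.

    ``edges``: bin boundaries t_0 < t_1 < ... < t_m; ``counts``: records in
    (t_{j-1}, t_j].  The likelihood conditions on a record falling inside
    (t_0, t_m].
    """
    a, b = params
    F = stats.logistic.cdf(a + b * edges)
    probs = np.diff(F)
    total = F[-1] - F[0]
    if total <= 0 or np.any(probs[counts > 0] <= 0):
        return -np.inf
    return float(np.sum(counts * np.log(np.maximum(probs, 1e-300))) - counts.sum() * np.log(total))


def _numeric_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def fit_inclusion_glm(
    curve: CumulativeCurve,
    origin_year: int,
    link: str = "logit",
    likelihood: str = "interval",
    conf_level: float = 0.95,
) -> FiellerEstimate:
    """Fit logit F(t) = a + b t to a pathway's inclusion curve and report the
    time to 50% inclusion t50 = -a/b with its Fieller confidence interval.

    ``likelihood="interval"`` (default) maximizes the interval-censored
    logistic likelihood of the yearly record increments, truncated to the
    observed window; ``likelihood="cumulative"`` reproduces the classical
    binomial pseudo-likelihood on the per-year cumulative counts.  Times are
    measured in years since ``origin_year``; the Fieller interval is valid
    when the g-condition g = z^2 var(b)/b^2 < 1 holds, otherwise the CI is
    reported as unbounded with ``g_condition_ok=False``.
    """
    if link not in ("logit", "probit"):
        raise ValueError("link must be 'logit' or 'probit'")
    if curve.transform != "none":
        raise ValueError("inclusion fits need untransformed counts")
    cum = np.asarray(curve.cumulative, dtype=float)
    n_total = int(cum[-1])
    if n_total < 10:
        raise ValueError(f"only {n_total} dated species; need >= 10")
    t = np.asarray(curve.years, dtype=float) - origin_year

    # start from the cumulative-count GLM in either case
    fam_link = sm.families.links.Logit() if link == "logit" else sm.families.links.Probit()
    endog = np.column_stack([cum, n_total - cum])
    exog = sm.add_constant(t)
    glm = sm.GLM(endog, exog, family=sm.families.Binomial(link=fam_link)).fit()
    a0, b0 = glm.params

    if likelihood == "cumulative":
        a, b = float(a0), float(b0)
        vcov = np.asarray(glm.cov_params())
    elif likelihood == "interval":
        if link != "logit":
            raise ValueError("interval likelihood is implemented for the logit link")
        counts = np.diff(cum, prepend=0.0)
        rec_years = t[counts > 0]
        rec_counts = counts[counts > 0]
        edges = np.concatenate([[rec_years[0] - 1.0], rec_years])
        nll = lambda p: -_interval_loglik(p, edges, rec_counts)
        res = optimize.minimize(nll, x0=[a0, b0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        res = optimize.minimize(nll, x0=res.x, method="BFGS")
        a, b = map(float, res.x)
        H = _numeric_hessian(nll, res.x)
        vcov = np.linalg.inv(H)
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")

    if b <= 0:
        raise ValueError("non-positive slope: the inclusion curve must rise")

    z = stats.norm.ppf(0.5 * (1 + conf_level))
    vaa, vab, vbb = vcov[0, 0], vcov[0, 1], vcov[1, 1]
    g = z**2 * vbb / b**2
    t50 = -a / b
    # Fieller: roots of (a + b*rho)^2 = z^2 (vaa + 2 rho vab + rho^2 vbb)
    A = b**2 - z**2 * vbb
    B = 2 * (a * b - z**2 * vab)
    C = a**2 - z**2 * vaa
    disc = B**2 - 4 * A * C
    if g < 1 and disc >= 0:
        lo = (-B - np.sqrt(disc)) / (2 * A)
        hi = (-B + np.sqrt(disc)) / (2 * A)
        ci_low, ci_high = float(min(lo, hi)), float(max(lo, hi))
        ok = True
    else:
        ci_low, ci_high = float("-inf"), float("inf")
        ok = False
    return FiellerEstimate(
        pathway=curve.pathway,
        t50=float(t50),
        ci_low=ci_low,
        ci_high=ci_high,
        glm_coefficients=(a, b),
        vcov=np.asarray(vcov),
        link=link,
        g=float(g),
        g_condition_ok=ok,
    )


def compare_inclusion(estimates: list[FiellerEstimate]) -> pd.DataFrame:
    """Pairwise rate comparison: pathways differ iff their t50 CIs are
    disjoint.  Symmetric; a pathway never differs from itself."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates to compare")
    names = [e.pathway for e in estimates]
    out = pd.DataFrame(False, index=names, columns=names, dtype=bool)
    for e1, e2 in combinations(estimates, 2):
        different = not e1.overlaps(e2)
        out.loc[e1.pathway, e2.pathway] = different
        out.loc[e2.pathway, e1.pathway] = different
    return out
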