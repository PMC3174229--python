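"""Linear mixed models for distribution and habitat range.

Responses are natural-log counts (occupied grid cells; occupied seminatural
or total habitat types) and the continuous covariate is square-root
residence time.  Species relatedness enters through random intercepts at
nested taxonomic ranks (genus in family in order); candidate random
structures are compared with REML likelihood-ratio tests whose reference
distribution is corrected for testing a variance on its boundary (the
0.5*chi2_0 + 0.5*chi2_1 mixture, i.e. half the nominal chi2_1 tail), and
the fixed structure is then reduced top-down with ML deletion tests before
a final REML refit.

Pathway enters fixed structures through membership contrasts (a species
introduced by several pathways belongs to each), mirroring the published
group contrasts: contaminant vs the rest, and {release, contaminant} vs
{escape, stowaway}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_data import PATHWAYS, STATUSES, FloraTable

__all__ = [
    "RANDOM_STRUCTURES",
    "ModelSpec",
    "MixedFit",
    "LrTestResult",
    "build_model_frame",
    "build_stacked_habitat_frame",
    "fit_mixed",
    "boundary_lr_test",
    "select_random_structure",
    "select_fixed_structure",
    "seminatural_contrasts",
    "diagnostics",
]

#: nested sequence of candidate random-intercept structures (plus the
#: non-nested genus-only alternative)
RANDOM_STRUCTURES = (
    "none",
    "order",
    "family_in_order",
    "genus_in_family_in_order",
    "genus_only",
)

_RESPONSES = ("log_grid_cells", "log_habitats_seminatural", "log_habitats")


@dataclass
class ModelSpec:
    """A mixed-model specification.

    ``fixed`` is a list of patsy-style terms (e.g. ``["status", "sqrt_rt",
    "status:sqrt_rt"]``); ``random`` is one of :data:`RANDOM_STRUCTURES`.
    ML is used for fixed-effect deletion tests, REML for random-structure
    tests and final reporting.
    """

    response: str = "log_habitats_seminatural"
    fixed: list = field(default_factory=lambda: ["sqrt_rt"])
    random: str = "none"
    estimation: str = "REML"

    def validate(self) -> None:
        if self.response not in _RESPONSES:
            raise ValueError(f"response must be one of {_RESPONSES}")
        if self.random not in RANDOM_STRUCTURES:
            raise ValueError(f"random must be one of {RANDOM_STRUCTURES}")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class MixedFit:
    spec: ModelSpec
    fixed_estimates: pd.DataFrame          # coef, se, tvalue per fixed term
    variance_components: dict              # per-level variance + "residual"
    loglik: float
    aic: float
    n: int
    data: pd.DataFrame                     # model frame used (for refits)
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.fixed_estimates) + len(self.variance_components)


@dataclass
class LrTestResult:
    statistic: float
    df_nominal: int
    p_value: float
    boundary_corrected: bool
    comparison: str = ""


# --------------------------------------------------------------------------
# model frame


def build_model_frame(table: FloraTable, zero_counts: str = "drop") -> pd.DataFrame:
    """One row per species with transformed responses and design columns.

    Counts are natural-log transformed; species with a zero count are
    dropped from the corresponding log response (``zero_counts="log1p"``
    switches to log(x+1) instead).  Residence time (years before the most
    recent first record in the table) enters as its square root.
    """
    rows = []
    for r in table:
        rows.append(
            {
                "species_id": r.species_id,
                "genus": r.genus,
                "family": r.family,
                "order": r.order,
                "status": r.status,
                "first_record_year": r.first_record_year,
                "grid_cells": r.grid_cells,
                "habitats_total": r.habitats_total,
                "habitats_seminatural": r.habitats_seminatural,
                **{f"is_{p}": (p in r.pathways) for p in PATHWAYS},
            }
        )
    df = pd.DataFrame(rows)
    ref_year = df["first_record_year"].max()
    df["sqrt_rt"] = np.sqrt(ref_year - df["first_record_year"])
    df["contaminant_vs_rest"] = df["is_contaminant"].astype(int)
    df["release_or_contaminant"] = (df["is_release"] | df["is_contaminant"]).astype(int)
    for count_col, log_col in (
        ("grid_cells", "log_grid_cells"),
        ("habitats_seminatural", "log_habitats_seminatural"),
        ("habitats_total", "log_habitats_total"),
    ):
        x = df[count_col].astype(float)
        if zero_counts == "log1p":
            df[log_col] = np.log1p(x)
        else:
            df[log_col] = np.where(x > 0, np.log(x.where(x > 0)), np.nan)
    return df


def build_stacked_habitat_frame(table: FloraTable) -> pd.DataFrame:
    """Long-format habitat range: two rows per species (total and
    seminatural counts) with a two-level ``habitat_type`` factor, for models
    where habitat type interacts with pathway and status.  The response
    column is ``log_habitats``."""
    wide = build_model_frame(table)
    blocks = []
    for htype, col in (("total", "log_habitats_total"),
                       ("seminatural", "log_habitats_seminatural")):
        block = wide.copy()
        block["habitat_type"] = htype
        block["log_habitats"] = block[col]
        blocks.append(block)
    long = pd.concat(blocks, ignore_index=True)
    return long.drop(columns=["log_habitats_total", "log_habitats_seminatural"])


def _check_nesting(df: pd.DataFrame) -> None:
    for child, parent in (("genus", "family"), ("family", "order")):
        if child not in df.columns or parent not in df.columns:
            continue
        n_parents = df.groupby(child, observed=True)[parent].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            raise ValueError(
                f"taxonomy not nested: {child} level(s) {list(bad.index[:5])} "
                f"appear under multiple {parent}s"
            )


# --------------------------------------------------------------------------
# fitting


def _ols_fit(df: pd.DataFrame, spec: ModelSpec) -> MixedFit:
    model = smf.ols(spec.formula, data=df)
    res = model.fit()
    n, p = int(res.nobs), len(res.params)
    if spec.estimation == "REML":
        # REML likelihood of the iid model, on the same convention as the
        # mixed-model REML likelihood (includes the ln|X'X| term)
        X = model.exog
        s2 = res.ssr / (n - p)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi) + 1 + np.log(s2))
            + np.linalg.slogdet(X.T @ X)[1]
        )
    else:
        ll = float(res.llf)
    fixed = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "tvalue": res.tvalues}
    )
    s2_ml = res.ssr / n if spec.estimation == "ML" else res.ssr / (n - p)
    vc = {"residual": float(s2_ml)}
    k = p + 1
    return MixedFit(
        spec=spec,
        fixed_estimates=fixed,
        variance_components=vc,
        loglik=float(ll),
        aic=-2 * float(ll) + 2 * k,
        n=n,
        data=df,
    )


def _oneway_fit(df: pd.DataFrame, spec: ModelSpec, group_col: str) -> MixedFit:
    """Exact profiled (RE)ML for a single random-intercept grouping.

    The likelihood is profiled over the fixed effects and the residual
    variance, leaving a one-dimensional optimization in the variance ratio
    lambda = var_group / var_residual; group-sum algebra makes each
    evaluation O(n).  The log-likelihood convention matches the general
    mixed-model fitter (REML includes the ln|X' V^-1 X| term), so values are
    directly comparable in nested LR tests.
    """
    import patsy
    from scipy import optimize as _opt

    y_mat, X_mat = patsy.dmatrices(spec.formula, df, return_type="dataframe")
    y = y_mat.to_numpy().ravel()
    X = X_mat.to_numpy()
    names = list(X_mat.columns)
    n, p = X.shape
    codes, _ = pd.factorize(df[group_col])
    G = codes.max() + 1
    n_g = np.bincount(codes, minlength=G).astype(float)
    Sx = np.zeros((G, p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=G)
    Sy = np.bincount(codes, weights=y, minlength=G)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    reml = spec.estimation == "REML"

    def profile(lam: float):
        a = lam / (1.0 + lam * n_g)
        XtVX = XtX - (Sx.T * a) @ Sx
        XtVy = Xty - Sx.T @ (a * Sy)
        yVy = yty - float(a @ Sy**2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yVy - float(beta @ XtVy), 1e-300)
        logdet_v0 = float(np.sum(np.log1p(lam * n_g)))
        if reml:
            # profiled REML: the -p*ln(s2) part of ln|X'V^-1 X| combines with
            # the n*ln(s2) from ln|V| into the (n-p)*ln(s2) term below
            s2 = rss / (n - p)
            ll = -0.5 * (
                (n - p) * (np.log(2 * np.pi) + 1 + np.log(s2))
                + logdet_v0
                + np.linalg.slogdet(XtVX)[1]
            )
        else:
            s2 = rss / n
            ll = -0.5 * (n * (np.log(2 * np.pi) + 1 + np.log(s2)) + logdet_v0)
        return ll, beta, s2, XtVX

    def neg_ll(theta: float) -> float:
        return -profile(np.exp(theta))[0]

    ll0 = profile(0.0)[0]
    res = _opt.minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                               options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    ll1 = -res.fun
    if ll0 >= ll1 - 1e-12:
        lam, ll = 0.0, ll0
    else:
        ll = ll1
    _, beta, s2, XtVX = profile(lam)
    cov_beta = s2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    fixed = pd.DataFrame({"coef": beta, "se": se, "tvalue": beta / se}, index=names)
    vc = {group_col: float(lam * s2), "residual": float(s2)}
    k = p + 2
    return MixedFit(
        spec=spec,
        fixed_estimates=fixed,
        variance_components=vc,
        loglik=float(ll),
        aic=-2 * float(ll) + 2 * k,
        n=n,
        data=df,
    )


def fit_mixed(
    table: FloraTable | pd.DataFrame, spec: ModelSpec, engine: str = "auto"
) -> MixedFit:
    """Fit the specified model; deterministic given the data.

    Rows missing the response or any model variable are dropped listwise.
    AIC counts fixed coefficients plus variance parameters (REML AICs are
    only comparable at a fixed fixed-structure).  Single random-intercept
    structures use an exact profiled-likelihood fitter by default
    (``engine="statsmodels"`` forces the general fitter; the two agree to
    numerical precision).
    """
    spec.validate()
    if isinstance(table, pd.DataFrame):
        df = table
    elif spec.response == "log_habitats":
        df = build_stacked_habitat_frame(table)
    else:
        df = build_model_frame(table)
    needed = {spec.response}
    for term in spec.fixed:
        needed.update(v.strip() for v in term.split(":"))
    needed = [c for c in needed if c in df.columns]
    df = df.dropna(subset=needed).copy()
    if len(df) < 30:
        raise ValueError(f"only {len(df)} usable species; need >= 30")
    _check_nesting(df)

    if spec.random == "none":
        return _ols_fit(df, spec)

    groups = {"order": "order", "family_in_order": "order",
              "genus_in_family_in_order": "order", "genus_only": "genus"}[spec.random]
    if engine == "auto" and spec.random in ("order", "genus_only"):
        return _oneway_fit(df, spec, groups)
    vc_formula = None
    if spec.random == "family_in_order":
        vc_formula = {"family": "0 + C(family)"}
    elif spec.random == "genus_in_family_in_order":
        vc_formula = {"family": "0 + C(family)", "genus": "0 + C(genus)"}
    model = smf.mixedlm(
        spec.formula, data=df, groups=df[groups], re_formula="1", vc_formula=vc_formula
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=(spec.estimation == "REML"))
    fixed = pd.DataFrame(
        {
            "coef": res.fe_params,
            "se": res.bse_fe,
            "tvalue": res.fe_params / res.bse_fe,
        }
    )
    vc = {groups if spec.random in ("order", "genus_only") else "order":
          float(res.cov_re.iloc[0, 0])}
    if vc_formula:
        for name in vc_formula:
            vc[f"{name}_in_order"] = float(res.vcomp[list(vc_formula).index(name)])
    vc["residual"] = float(res.scale)
    k = len(fixed) + len(vc)
    ll = float(res.llf)
    return MixedFit(
        spec=spec,
        fixed_estimates=fixed,
        variance_components=vc,
        loglik=ll,
        aic=-2 * ll + 2 * k,
        n=int(res.nobs),
        data=df,
        converged=bool(res.converged),
    )


def boundary_lr_test(
    ll_null: float, ll_alt: float, comparison: str = ""
) -> LrTestResult:
    """LR test for one added variance component tested on its boundary.

    The reference distribution is the equal mixture of chi2_0 and chi2_1, so
    the corrected p-value is half the nominal chi2_1 tail probability.
    """
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = 0.5 * float(stats.chi2.sf(stat, 1))
    return LrTestResult(
        statistic=stat, df_nominal=1, p_value=p, boundary_corrected=True,
        comparison=comparison,
    )


# --------------------------------------------------------------------------
# structure selection


def select_random_structure(
    table: FloraTable | pd.DataFrame,
    beyond_optimal_fixed: ModelSpec,
    alpha: float = 0.05,
) -> tuple[str, list[LrTestResult], pd.DataFrame]:
    """Forward REML LR tests along none -> order -> family-in-order ->
    genus-in-family-in-order, each step adding one variance component with a
    boundary-corrected reference distribution.

    If the full hierarchy wins, it is additionally compared with the
    non-nested genus-only structure by AIC.  The returned AIC table covers
    all candidates; disagreement between the LR-based choice and the AIC
    minimum is flagged in the table attribute ``aic_agrees``.
    """
    nested = ["none", "order", "family_in_order", "genus_in_family_in_order"]
    fits = {}
    for r in nested + ["genus_only"]:
        spec = replace(beyond_optimal_fixed, random=r, estimation="REML")
        try:
            fits[r] = fit_mixed(table, spec)
        except (np.linalg.LinAlgError, ValueError):
            # a redundant level (e.g. every family holding one genus) can
            # make a richer structure unidentifiable; drop that candidate
            continue
    tests: list[LrTestResult] = []
    chosen = "none"
    for simpler, richer in zip(nested[:-1], nested[1:]):
        if simpler not in fits or richer not in fits:
            break
        t = boundary_lr_test(
            fits[simpler].loglik, fits[richer].loglik, f"{richer} vs {simpler}"
        )
        tests.append(t)
        if t.p_value < alpha:
            chosen = richer
        else:
            break
    if chosen == "genus_in_family_in_order" and "genus_only" in fits:
        if fits["genus_only"].aic < fits["genus_in_family_in_order"].aic:
            chosen = "genus_only"
    aic = pd.DataFrame(
        {
            "aic": {r: fits[r].aic for r in fits},
            "reml_loglik": {r: fits[r].loglik for r in fits},
        }
    )
    aic.attrs["aic_agrees"] = aic["aic"].idxmin() == chosen
    return chosen, tests, aic


def _term_order(term: str) -> int:
    return term.count(":") + 1


def _contains(bigger: str, smaller: str) -> bool:
    return set(smaller.split(":")) < set(bigger.split(":"))


def select_fixed_structure(
    table: FloraTable | pd.DataFrame,
    random_structure: str,
    beyond_optimal_fixed: ModelSpec,
    alpha: float = 0.05,
) -> tuple[ModelSpec, list[LrTestResult]]:
    """Top-down ML deletion tests toward the minimum adequate fixed model.

    At each step every term of the current highest interaction order is
    tested by an ML LR deletion test with the other same-order terms still
    in the model; the least significant non-significant term is removed.
    Terms contained in a surviving higher-order interaction are never
    tested.  The returned spec is refit-ready with REML estimation.
    """
    df = table if isinstance(table, pd.DataFrame) else build_model_frame(table)
    terms = list(beyond_optimal_fixed.fixed)
    trail: list[LrTestResult] = []

    def fit_with(fixed_terms: list) -> MixedFit:
        spec = replace(
            beyond_optimal_fixed,
            fixed=list(fixed_terms),
            random=random_structure,
            estimation="ML",
        )
        return fit_mixed(df, spec)

    current = fit_with(terms)
    while terms:
        protected = {
            t for t in terms if any(_contains(b, t) for b in terms if b != t)
        }
        candidates = [t for t in terms if t not in protected]
        if not candidates:
            break
        top = max(_term_order(t) for t in candidates)
        candidates = [t for t in candidates if _term_order(t) == top]
        results = []
        for t in candidates:
            reduced = fit_with([x for x in terms if x != t])
            lr = max(0.0, 2.0 * (current.loglik - reduced.loglik))
            p = float(stats.chi2.sf(lr, max(1, len(current.fixed_estimates) - len(reduced.fixed_estimates))))
            results.append((p, t, reduced, lr))
        results.sort(key=lambda r: -r[0])
        p, t, reduced, lr = results[0]
        trail.append(
            LrTestResult(
                statistic=lr,
                df_nominal=len(current.fixed_estimates) - len(reduced.fixed_estimates),
                p_value=p,
                boundary_corrected=False,
                comparison=f"drop {t}",
            )
        )
        if p >= alpha:
            terms = [x for x in terms if x != t]
            current = reduced
        else:
            break
    final = replace(
        beyond_optimal_fixed, fixed=terms, random=random_structure, estimation="REML"
    )
    return final, trail


# --------------------------------------------------------------------------
# contrasts and diagnostics


def seminatural_contrasts(fit: MixedFit) -> dict:
    """Back-transformed group means and the published pathway contrasts.

    Means on the natural scale come from exponentiating fitted log-means.
    Two deletion tests are reported (where the grouping column varies in the
    data): contaminant vs the other pathways, and {release, contaminant} vs
    {escape, stowaway}; each is an ML LR test of dropping the contrast.
    """
    if not fit.spec.response.startswith("log_habitats"):
        raise ValueError("contrasts are defined for habitat-range responses")
    df = fit.data
    out: dict = {"group_means": {}, "tests": {}}
    for col in ("contaminant_vs_rest", "release_or_contaminant"):
        if col not in df.columns or df[col].nunique() < 2:
            continue
        means = {}
        for level, sub in df.groupby(col):
            means[int(level)] = float(np.exp(sub[fit.spec.response].mean()))
        out["group_means"][col] = means
        with_term = replace(
            fit.spec,
            fixed=sorted(set(fit.spec.fixed) | {col}),
            estimation="ML",
        )
        without_term = replace(
            fit.spec,
            fixed=[t for t in with_term.fixed if t != col],
            estimation="ML",
        )
        full = fit_mixed(df, with_term)
        red = fit_mixed(df, without_term)
        lr = max(0.0, 2.0 * (full.loglik - red.loglik))
        out["tests"][col] = LrTestResult(
            statistic=lr,
            df_nominal=1,
            p_value=float(stats.chi2.sf(lr, 1)),
            boundary_corrected=False,
            comparison=f"deletion of {col}",
        )
    out["back_transformed_overall_mean"] = float(
        np.exp(df[fit.spec.response].mean())
    )
    return out


def diagnostics(fit: MixedFit) -> dict:
    """Residual checks: standardized residuals vs fitted, and normality.

    Fitted values are conditional (fixed part plus BLUP-shrunken random
    intercepts), so the check regression of standardized residuals on
    fitted values has slope ~0 for a well-specified model; the normal-
    quantile correlation of the residuals is near 1 for Gaussian noise.
    """
    import patsy

    df = fit.data
    y, X = patsy.dmatrices(fit.spec.formula, df, return_type="dataframe")
    coef = fit.fixed_estimates["coef"].reindex(X.columns).to_numpy()
    fitted = X.to_numpy() @ coef
    resid = y.to_numpy().ravel() - fitted
    # sequentially shrink group means toward zero by n_g / (n_g + s2/v):
    # the exact BLUP for one grouping, a good approximation for nesting
    s2 = fit.variance_components.get("residual", float(np.var(resid)))
    level_col = {"order": "order", "family_in_order": "family",
                 "genus_in_order": "genus", "genus": "genus"}
    for comp, v in fit.variance_components.items():
        col = level_col.get(comp)
        if col is None or v <= 0 or col not in df.columns:
            continue
        groups = df[col].to_numpy()
        resid_s = pd.Series(resid)
        means = resid_s.groupby(groups).transform("mean").to_numpy()
        sizes = pd.Series(np.ones(len(df))).groupby(groups).transform("sum").to_numpy()
        blup = sizes / (sizes + s2 / v) * means
        fitted = fitted + blup
        resid = resid - blup
    sd = np.std(resid, ddof=1)
    std_resid = resid / sd if sd > 0 else resid
    if np.ptp(fitted) > 0:
        slope = float(np.polyfit(fitted, std_resid, 1)[0])
    else:
        slope = 0.0
    n = len(std_resid)
    osm = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    osr = np.sort(std_resid)
    nq_corr = float(np.corrcoef(osm, osr)[0, 1]) if n > 2 and sd > 0 else 1.0
    return {
        "standardized_residuals": std_resid,
        "check_regression_slope": slope,
        "normal_quantile_correlation": nq_corr,
    }
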