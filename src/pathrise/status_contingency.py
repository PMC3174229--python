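"""Pathway x invasion-status contingency analysis.

A multi-label species contributes one count to every pathway it was
introduced by, so the 4 x 3 table's grand total exceeds the number of
species.  Independence of pathway and status is tested with the G statistic,
computed both in closed form, G = 2 * sum O * ln(O/E), and as the deviance
drop from adding the row x column interaction to a Poisson log-linear model
(the two must agree).  Cell-level departures are judged by adjusted
standardized residuals, which are approximately standard normal under
independence.  A three-way deletion test checks whether the pathway x status
association changed between species introduced before and after a split year
(residence-time effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_data import PATHWAYS, STATUSES, FloraTable

__all__ = [
    "ContingencyResult",
    "ThreeWayTestResult",
    "build_table",
    "g_test",
    "adjusted_residuals",
    "status_proportions",
    "residence_time_interaction_test",
]

#: two-sided normal critical values for the residual significance flags
_FLAG_LEVELS = (
    (3.291, "***"),  # P < 0.001
    (2.576, "**"),   # P < 0.01
    (1.960, "*"),    # P < 0.05
    (1.645, "(*)"),  # P < 0.1
)


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    g_statistic: float
    df: int
    p_value: float
    adjusted_residuals: pd.DataFrame
    flags: pd.DataFrame
    g_from_loglinear: float = field(default=float("nan"))

    def __str__(self) -> str:  # Table-1-style text rendering
        lines = [f"G = {self.g_statistic:.3f}, df = {self.df}, P = {self.p_value:.3g}"]
        for r in self.observed.index:
            cells = [
                f"{self.observed.loc[r, c]:>4d} ({self.expected.loc[r, c]:6.1f}){self.flags.loc[r, c]:<3s}"
                for c in self.observed.columns
            ]
            lines.append(f"{r:<12s} " + "  ".join(cells))
        return "\n".join(lines)


@dataclass
class ThreeWayTestResult:
    chi_sq: float
    df: int
    p_value: float
    period_split_year: int
    subset_sizes: tuple


def build_table(table: FloraTable) -> pd.DataFrame:
    """4 x 3 observed counts; each species counts once per pathway it has."""
    counts = pd.DataFrame(0, index=list(PATHWAYS), columns=list(STATUSES), dtype=int)
    for rec in table:
        for p in rec.pathways:
            counts.loc[p, rec.status] += 1
    return counts


def expected_counts(observed: pd.DataFrame) -> pd.DataFrame:
    obs = observed.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    return pd.DataFrame(row @ col / total, index=observed.index, columns=observed.columns)


def g_test(observed: pd.DataFrame) -> ContingencyResult:
    """G-test of independence on an R x C count table.

    Expected counts are the usual product-margin values; cells with O = 0
    contribute nothing to G (the x*ln(x) -> 0 limit).  The closed-form G is
    cross-checked against the Poisson log-linear deviance drop and the two
    are required to agree to 1e-6.
    """
    observed = pd.DataFrame(observed).astype(int)
    obs = observed.to_numpy(dtype=float)
    if (obs.sum(axis=1) <= 0).any():
        bad = observed.index[obs.sum(axis=1) <= 0].tolist()
        raise ValueError(f"zero row total(s) for {bad}")
    if (obs.sum(axis=0) <= 0).any():
        bad = observed.columns[obs.sum(axis=0) <= 0].tolist()
        raise ValueError(f"zero column total(s) for {bad}")
    expected = expected_counts(observed)
    exp = expected.to_numpy()
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    g_ll = _g_from_loglinear(observed)
    if abs(g - g_ll) > 1e-6:
        raise AssertionError(
            f"closed-form G ({g}) and log-linear deviance drop ({g_ll}) disagree"
        )
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(g, df))
    resid, flags = adjusted_residuals(observed, expected)
    return ContingencyResult(
        observed=observed,
        expected=expected,
        g_statistic=g,
        df=df,
        p_value=p,
        adjusted_residuals=resid,
        flags=flags,
        g_from_loglinear=g_ll,
    )


def _g_from_loglinear(observed: pd.DataFrame) -> float:
    """Deviance drop when the row x column interaction enters the Poisson
    log-linear model (the saturated model has deviance zero)."""
    long = observed.stack().rename("count").reset_index()
    long.columns = ["row", "col", "count"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturated-model separation notices
        main = smf.glm(
            "count ~ C(row) + C(col)", data=long, family=sm.families.Poisson()
        ).fit()
    return float(main.deviance)


def adjusted_residuals(
    observed: pd.DataFrame, expected: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted standardized residuals with two-sided significance flags.

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - rowtot_i/N) (1 - coltot_j/N)),
    compared against normal critical values 1.645 / 1.960 / 2.576 / 3.291
    for the 0.1 / 0.05 / 0.01 / 0.001 levels.
    """
    obs = pd.DataFrame(observed).to_numpy(dtype=float)
    exp = pd.DataFrame(expected).to_numpy(dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True) / n
    col = obs.sum(axis=0, keepdims=True) / n
    denom_sq = exp * (1.0 - row) * (1.0 - col)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom_sq > 0, (obs - exp) / np.sqrt(denom_sq), np.nan)
    flags = np.empty(r.shape, dtype=object)
    flags[:] = ""
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if not np.isfinite(r[i, j]):
                flags[i, j] = "undef"
                continue
            for crit, mark in _FLAG_LEVELS:
                if abs(r[i, j]) >= crit:
                    flags[i, j] = mark
                    break
    idx = pd.DataFrame(observed).index
    cols = pd.DataFrame(observed).columns
    return (
        pd.DataFrame(r, index=idx, columns=cols),
        pd.DataFrame(flags, index=idx, columns=cols),
    )


def status_proportions(table: FloraTable | pd.DataFrame) -> pd.DataFrame:
    """Per-pathway status percentages (one decimal) with the combined
    naturalized-or-invasive share; denominators are per-pathway totals."""
    observed = table if isinstance(table, pd.DataFrame) else build_table(table)
    obs = observed.to_numpy(dtype=float)
    totals = obs.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pct = np.where(totals > 0, 100.0 * obs / totals, 0.0)
    out = pd.DataFrame(
        np.round(pct, 1), index=observed.index, columns=[f"{c}_pct" for c in observed.columns]
    )
    # combined share as the sum of the rounded components (the convention
    # used when such percentages are printed side by side)
    out["naturalized_or_invasive_pct"] = np.round(
        out["naturalized_pct"] + out["invasive_pct"], 1
    )
    out["n"] = totals.astype(int)
    return out


def residence_time_interaction_test(
    table: FloraTable, split_year: int = 1900
) -> ThreeWayTestResult:
    """Deletion test of the pathway x status x period three-way interaction.

    Species with a known first-record year are split at ``split_year``; the
    statistic is the deviance difference between the Poisson log-linear model
    with all two-way interactions and the saturated model on the 4 x 3 x 2
    table, on (R-1)(C-1)(T-1) = 6 degrees of freedom.  A non-significant
    result means the pathway-status association is stable across the two
    introduction periods.
    """
    dated = [r for r in table if r.first_record_year is not None]
    n_before = sum(r.first_record_year < split_year for r in dated)
    n_after = len(dated) - n_before
    if n_before == 0 or n_after == 0:
        raise ValueError(f"no dated species on one side of {split_year}")
    rows = []
    for p in PATHWAYS:
        for s in STATUSES:
            for period in ("before", "after"):
                count = sum(
                    1
                    for r in dated
                    if p in r.pathways
                    and r.status == s
                    and (r.first_record_year < split_year) == (period == "before")
                )
                rows.append({"pathway": p, "status": s, "period": period, "count": count})
    long = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        two_way = smf.glm(
            "count ~ (C(pathway) + C(status) + C(period)) ** 2",
            data=long,
            family=sm.families.Poisson(),
        ).fit()
    chi_sq = float(two_way.deviance)  # saturated model has deviance 0
    df = (len(PATHWAYS) - 1) * (len(STATUSES) - 1) * 1
    return ThreeWayTestResult(
        chi_sq=chi_sq,
        df=df,
        p_value=float(stats.chi2.sf(chi_sq, df)),
        period_split_year=split_year,
        subset_sizes=(n_before, n_after),
    )
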