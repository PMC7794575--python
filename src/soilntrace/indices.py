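"""Derived N-cycling indices and cohort statistics.

Indices (all dimensionless ratios of 48-h average gross rates, except the
inorganic-N ratio which uses measured concentrations):

* nitrification capacity   = O_NH4 / M_N
* NO3- retention capacity  = (I_NO3 + D_NO3) / (O_NH4 + O_Nrec)
* O/I ratio                = O_NH4 / I_NH4
* NO3-/NH4+ ratio          = soil NO3- conc / NH4+ conc

A ratio with a zero denominator is *undefined* (NaN + flag), never silently
zero.  Group comparisons between land uses use the independent-samples t test
(equal-variance by default, Welch optional) with a Kolmogorov-Smirnov
normality check (Lilliefors variant, since group moments are estimated)
attached per group; the normality result is reported but never gates the
t test.  Pairwise relationships use Pearson product-moment correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import GrossRates

__all__ = [
    "DerivedIndices",
    "derive_indices",
    "GroupComparison",
    "compare_groups",
    "CorrelationResult",
    "correlate",
    "LAND_USES",
]

LAND_USES = ("forestland", "cropland")

INDEX_NAMES = (
    "nitrification_capacity",
    "no3_retention_capacity",
    "o_over_i",
    "no3_nh4_ratio",
)


@dataclass(frozen=True)
class DerivedIndices:
    nitrification_capacity: float
    no3_retention_capacity: float
    o_over_i: float
    no3_nh4_ratio: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def is_defined(self, name: str) -> bool:
        if name not in INDEX_NAMES:
            raise KeyError(name)
        return name not in self.undefined

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0.0:
        undefined.add(name)
        return math.nan
    return num / den


def derive_indices(
    rates: GrossRates,
    nh4_conc: float | None = None,
    no3_conc: float | None = None,
) -> DerivedIndices:
    """Compute the four ratios from one soil's gross rates (and, for the
    NO3-/NH4+ ratio, its measured inorganic N concentrations; omitted when
    concentrations are not supplied)."""
    undefined: set[str] = set()
    nc = _ratio(rates.rate("O_NH4"), rates.m_n, "nitrification_capacity", undefined)
    rc = _ratio(
        rates.rate("I_NO3") + rates.rate("D_NO3"),
        rates.rate("O_NH4") + rates.rate("O_Nrec"),
        "no3_retention_capacity",
        undefined,
    )
    oi = _ratio(rates.rate("O_NH4"), rates.i_nh4, "o_over_i", undefined)
    if nh4_conc is None or no3_conc is None:
        undefined.add("no3_nh4_ratio")
        rr = math.nan
    else:
        if nh4_conc < 0 or no3_conc < 0:
            raise ValueError("concentrations must be >= 0")
        rr = _ratio(no3_conc, nh4_conc, "no3_nh4_ratio", undefined)
    return DerivedIndices(nc, rc, oi, rr, undefined=frozenset(undefined))


# --------------------------------------------------------------------------
# Group statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    t: float
    p: float
    df: float
    means: tuple[float, float]
    ses: tuple[float, float]
    n: tuple[int, int]
    ks_stat: tuple[float, float]  # Lilliefors KS statistic per group
    ks_p: tuple[float, float]
    equal_var: bool

    @property
    def significant(self) -> bool:
        """At the conventional 0.05 level."""
        return self.p < 0.05


def _ks_normality(x: np.ndarray) -> tuple[float, float]:
    # the Lilliefors table starts at n = 4; smaller groups get no verdict
    if len(x) < 4 or np.std(x, ddof=1) == 0:
        return math.nan, math.nan
    from statsmodels.stats.diagnostic import lilliefors

    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "land_use",
    groups: Sequence[str] = LAND_USES,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided independent-samples t test of ``variable`` between the two
    land-use groups (first minus second), with per-group KS normality
    attached.  Rows with an undefined (NaN) value are excluded pairwise.
    Groups with < 2 usable samples raise."""
    if variable not in cohort.columns:
        raise KeyError(variable)
    ga, gb = groups
    a = cohort.loc[cohort[group_col] == ga, variable].dropna().to_numpy(float)
    b = cohort.loc[cohort[group_col] == gb, variable].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples ({ga}: {len(a)}, {gb}: {len(b)})"
        )
    mean_a, mean_b = a.mean(), b.mean()
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        # degenerate: no within-group scatter at all
        t_stat, p_val = (0.0, 1.0) if mean_a == mean_b else (math.inf, 0.0)
        dof = float(len(a) + len(b) - 2)
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
        if equal_var:
            dof = float(len(a) + len(b) - 2)
        else:
            na, nb = len(a), len(b)
            dof = (var_a / na + var_b / nb) ** 2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
    return GroupComparison(
        variable=variable,
        groups=(ga, gb),
        t=float(t_stat),
        p=float(p_val),
        df=dof,
        means=(float(mean_a), float(mean_b)),
        ses=(
            float(np.std(a, ddof=1) / math.sqrt(len(a))),
            float(np.std(b, ddof=1) / math.sqrt(len(b))),
        ),
        n=(len(a), len(b)),
        ks_stat=(_ks_normality(a)[0], _ks_normality(b)[0]),
        ks_p=(_ks_normality(a)[1], _ks_normality(b)[1]),
        equal_var=equal_var,
    )


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int


def correlate(cohort: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson product-moment correlation between two cohort variables with a
    two-sided p value; NaN rows excluded pairwise; zero variance raises."""
    for col in (x, y):
        if col not in cohort.columns:
            raise KeyError(col)
    sub = cohort[[x, y]].dropna()
    xv = sub[x].to_numpy(float)
    yv = sub[y].to_numpy(float)
    if len(sub) < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got {len(sub)}")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in a correlation variable")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(x=x, y=y, r=float(r), p=float(p), n=len(sub))


def stats_report(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    correlations: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience batch runner: group comparisons for ``variables`` and
    Pearson correlations for the requested pairs, as two tidy tables."""
    comp_rows = []
    for v in variables:
        c = compare_groups(cohort, v)
        comp_rows.append(
            {
                "variable": v,
                "mean_" + c.groups[0]: c.means[0],
                "se_" + c.groups[0]: c.ses[0],
                "mean_" + c.groups[1]: c.means[1],
                "se_" + c.groups[1]: c.ses[1],
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "ks_p_" + c.groups[0]: c.ks_p[0],
                "ks_p_" + c.groups[1]: c.ks_p[1],
            }
        )
    corr_rows = []
    for xv, yv in correlations:
        r = correlate(cohort, xv, yv)
        corr_rows.append({"x": xv, "y": yv, "r": r.r, "p": r.p, "n": r.n})
    return pd.DataFrame(comp_rows), pd.DataFrame(corr_rows)
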