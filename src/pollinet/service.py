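"""Pollination-service estimation: visits x single-visit deposition.

Total conspecific pollen deposition on the focal plant is estimated per
insect taxon and week as (number of visits to the focal plant, from the
weekly visitation networks) x (mean single-visit deposition, SVD). SVD
means are taken per insect genus where trials exist and per family
otherwise; taxa with neither are excluded and logged. Control (unvisited)
flower deposition is summarized alongside but never subtracted.

Pollen *transport* (removal from all plants) is estimated from the pollen
loads on captured insects: the mean load of a plant genus over a taxon's
captured individuals, scaled by the number of individuals captured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .networks import NetworkSeries
from .records import TaxonomyMap

__all__ = [
    "SVDTable",
    "RegressionResult",
    "svd_table",
    "estimate_service",
    "annual_service",
    "community_total",
    "activity_periods",
    "estimate_transport",
    "fit_line",
    "service_vs_activity",
]

log = logging.getLogger(__name__)

SERVICE_COLUMNS = [
    "insect_taxon",
    "year",
    "week",
    "visits",
    "svd_mean",
    "estimated_grains",
    "svd_level",
]


@dataclass
class SVDTable:
    """Single-visit deposition means at genus and family level.

    Family means pool every non-control trial of the family, including
    genus-resolved ones; the control summary describes pollen found on
    unvisited flowers (background contamination).
    """

    genus: pd.DataFrame  # genus, mean, sd, n
    family: pd.DataFrame  # family, mean, sd, n
    control: dict  # n, mean, median, sd

    def lookup(self, genus: str | None, family: str | None):
        """(mean, level) with genus preferred and family fallback; None if
        neither is available."""
        if genus is not None:
            row = self.genus[self.genus["genus"] == genus]
            if len(row):
                return float(row["mean"].iloc[0]), "genus"
        if family is not None:
            row = self.family[self.family["family"] == family]
            if len(row):
                return float(row["mean"].iloc[0]), "family"
        return None, None


def svd_table(obs: pd.DataFrame) -> SVDTable:
    """Aggregate raw SVD trials (schema ``svd``) into genus/family means and
    a control summary."""
    trials = obs[~obs["is_control"]]
    if trials.empty:
        raise ValueError("no non-control SVD observations")
    with_genus = trials[trials["genus"].astype(str).str.strip() != ""]
    genus = (
        with_genus.groupby("genus")["grains"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    family = (
        trials.groupby("family")["grains"].agg(mean="mean", sd="std", n="count").reset_index()
    )
    controls = obs.loc[obs["is_control"], "grains"]
    control = {
        "n": int(len(controls)),
        "mean": float(controls.mean()) if len(controls) else None,
        "median": float(controls.median()) if len(controls) else None,
        "sd": float(controls.std(ddof=1)) if len(controls) > 1 else None,
    }
    return SVDTable(genus=genus, family=family, control=control)


def estimate_service(
    nets: NetworkSeries,
    svd: SVDTable,
    focal_plant: str,
    taxmap: TaxonomyMap | None = None,
) -> pd.DataFrame:
    """Weekly deposition estimates: visits to the focal plant x SVD mean.

    ``taxmap`` resolves each visiting insect taxon to the genus and family
    used for the SVD lookup; without one, the taxon name is used as its own
    genus and no family fallback is possible. Taxa lacking both SVD levels
    are excluded (logged once each).
    """
    rows = []
    excluded: set[str] = set()
    seen_focal = False
    for (year, week), net in nets:
        if focal_plant not in net.plants:
            continue
        seen_focal = True
        r = net.plants.index(focal_plant)
        for c, insect in enumerate(net.insects):
            visits = net.weights[r, c]
            if visits <= 0:
                continue
            if taxmap is not None and insect in taxmap:
                genus = taxmap.genus_of(insect)
                family = taxmap.family(insect)
            else:
                genus, family = insect, None
            mean, level = svd.lookup(genus, family)
            if mean is None:
                excluded.add(insect)
                continue
            rows.append(
                {
                    "insect_taxon": insect,
                    "year": year,
                    "week": week,
                    "visits": int(visits),
                    "svd_mean": mean,
                    "estimated_grains": float(visits) * mean,
                    "svd_level": level,
                }
            )
    if not seen_focal:
        raise ValueError(f"focal plant {focal_plant!r} absent from every network")
    for taxon in sorted(excluded):
        log.warning("no genus- or family-level SVD for %s; excluded from service", taxon)
    return pd.DataFrame(rows, columns=SERVICE_COLUMNS)


def annual_service(weekly: pd.DataFrame) -> pd.DataFrame:
    """Annual per-taxon deposition totals (exact sums of the weekly rows)."""
    if weekly.empty:
        return pd.DataFrame(columns=["insect_taxon", "year", "visits", "estimated_grains"])
    return (
        weekly.groupby(["insect_taxon", "year"], as_index=False)
        .agg(visits=("visits", "sum"), estimated_grains=("estimated_grains", "sum"))
        .sort_values(["insect_taxon", "year"])
        .reset_index(drop=True)
    )


def community_total(weekly: pd.DataFrame) -> float:
    """Total estimated deposition summed over all taxa with SVD data."""
    return float(weekly["estimated_grains"].sum())


def activity_periods(records: pd.DataFrame) -> pd.DataFrame:
    """Mean number of distinct weeks per year in which each insect taxon was
    observed (its activity/flight period, averaged over the years in which
    it appeared at all)."""
    if records.empty:
        raise ValueError("no interaction records")
    per_year = (
        records.groupby(["insect_taxon", "year"])["week"].nunique().rename("weeks").reset_index()
    )
    out = per_year.groupby("insect_taxon", as_index=False)["weeks"].mean()
    return out.rename(columns={"weeks": "activity_weeks"})


def estimate_transport(pollen: pd.DataFrame, nets: NetworkSeries | None = None) -> pd.DataFrame:
    """Weekly pollen-transport estimates from the loads on captured insects.

    ``mean_load`` is the mean number of grains of the plant genus over the
    taxon's captured individuals that week (individuals captured without
    that pollen count as zeros); ``estimated_removed = mean_load *
    n_individuals`` scales back to the taxon's observed sample. The rule is
    a documented per-individual convention (flagged in output metadata by
    the pipeline).
    """
    if pollen.empty:
        raise ValueError("no pollen-load records")
    captured = (
        pollen.groupby(["insect", "year", "week"])["individual"]
        .nunique()
        .rename("n_individuals")
        .reset_index()
    )
    loads = (
        pollen[pollen["grains"] > 0]
        .groupby(["insect", "year", "week", "plant_genus"], as_index=False)["grains"]
        .sum()
    )
    out = loads.merge(captured, on=["insect", "year", "week"])
    out["mean_load"] = out["grains"] / out["n_individuals"]
    out["estimated_removed"] = out["mean_load"] * out["n_individuals"]
    out = out.rename(columns={"insect": "insect_taxon", "plant_genus": "plant"})
    return out[
        ["insect_taxon", "plant", "year", "week", "mean_load", "n_individuals", "estimated_removed"]
    ].sort_values(["insect_taxon", "plant", "year", "week"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# regressions

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_slope: float
    n: int
    dropped_terms: list[str] = field(default_factory=list)
    coefficients: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "p_slope": self.p_slope,
            "n": self.n,
            "dropped_terms": self.dropped_terms,
            "coefficients": self.coefficients,
        }


def fit_line(x, y) -> RegressionResult:
    """Simple OLS from the normal equations, with the two-sided t test for
    the slope (df = n - 2) and both multiple and adjusted R^2.

    A negative adjusted R^2 is reported as-is.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y lengths differ")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("x has zero variance")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2, adj_r2, p = 0.0, 0.0, 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        sigma2 = ss_res / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        if se == 0:
            p = 0.0
        else:
            tval = slope / se
            p = float(2 * stats.t.sf(abs(tval), df=n - 2))
    return RegressionResult(
        slope=float(slope),
        intercept=intercept,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        p_slope=float(p),
        n=n,
        coefficients={"intercept": intercept, "slope": float(slope)},
    )


def service_vs_activity(
    annual: pd.DataFrame,
    activity: pd.DataFrame,
    alpha: float = 0.05,
) -> RegressionResult:
    """Deposition ~ activity period, after stepwise simplification.

    Starts from deposition ~ activity * year (year centered, continuous) and
    drops nonsignificant terms at ``alpha``, interaction first, then the
    year main effect; the reported slope/p are for the activity term of the
    final model.
    """
    df = annual.merge(activity, on="insect_taxon")
    if len(df) < 3:
        raise ValueError(f"need >= 3 taxon-year rows, got {len(df)}")
    y = df["estimated_grains"].to_numpy(dtype=float)
    act = df["activity_weeks"].to_numpy(dtype=float)
    yr = df["year"].to_numpy(dtype=float)
    yr = yr - yr.mean()
    dropped: list[str] = []
    terms = ["activity", "year", "activity:year"]
    design = {"activity": act, "year": yr, "activity:year": act * yr}

    def _fit(current):
        X = sm.add_constant(np.column_stack([design[t] for t in current]))
        return sm.OLS(y, X).fit()

    if np.ptp(yr) == 0:
        # single year: no year or interaction terms are estimable
        dropped.extend(["activity:year", "year"])
        terms = ["activity"]
        res = _fit(terms)
    else:
        res = _fit(terms)
        if res.pvalues[terms.index("activity:year") + 1] > alpha:
            dropped.append("activity:year")
            terms = ["activity", "year"]
            res = _fit(terms)
            if res.pvalues[terms.index("year") + 1] > alpha:
                dropped.append("year")
                terms = ["activity"]
                res = _fit(terms)
    act_idx = terms.index("activity") + 1
    coeffs = {"intercept": float(res.params[0])}
    coeffs.update({t: float(res.params[k + 1]) for k, t in enumerate(terms)})
    return RegressionResult(
        slope=float(res.params[act_idx]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        p_slope=float(res.pvalues[act_idx]),
        n=len(df),
        dropped_terms=dropped,
        coefficients=coeffs,
    )
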