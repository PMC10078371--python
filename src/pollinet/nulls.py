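"""Metaweb-resampling null models and cross-method metric correlations.

The null model draws "same-size" random networks from a source web (the
metaweb for annual tests, the annual web for weekly tests): species are
drawn uniformly without replacement to match the observed plant and insect
counts, the link set is the induced subgraph of the source links (so link
number varies with the species drawn), and each present link's strength is
drawn from a uniform distribution spanning the range of observed strengths.
An observed metric is significantly nonrandom if it falls below the 0.025
or above the 0.975 empirical quantile of 1000 replicate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import UndefinedMetric, METRIC_FUNCS, modularity
from .networks import BipartiteNetwork, NetworkSeries

__all__ = [
    "NullDistribution",
    "CorrelationReport",
    "sample_same_size",
    "null_distribution",
    "weekly_vs_annual",
    "annual_vs_metaweb",
    "correlate_metrics",
    "calibration_rejection_rate",
    "NULL_METRICS",
]


def _metric_n_links(net: BipartiteNetwork) -> float:
    return float(net.n_links)


def _metric_n_plants(net: BipartiteNetwork) -> float:
    return float(net.pruned().n_plants)


def _metric_n_insects(net: BipartiteNetwork) -> float:
    return float(net.pruned().n_insects)


#: metric name -> callable(net) -> float; replicates are pruned of isolated
#: species before evaluation, exactly as observed networks are.
NULL_METRICS = dict(METRIC_FUNCS)
NULL_METRICS.update(
    {
        "n_links": _metric_n_links,
        "n_plants": _metric_n_plants,
        "n_insects": _metric_n_insects,
    }
)


@dataclass
class NullDistribution:
    metric: str
    source_label: str
    observed: float | None
    replicates: np.ndarray
    q_low: float | None
    q_high: float | None
    verdict: str  # low | high | ns | undefined
    seed: int
    n_discarded_empty: int = 0
    n_undefined: int = 0

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "source": self.source_label,
            "observed": self.observed,
            "q025": self.q_low,
            "q975": self.q_high,
            "verdict": self.verdict,
            "n_replicates": len(self.replicates),
            "n_discarded_empty": self.n_discarded_empty,
            "n_undefined": self.n_undefined,
            "seed": self.seed,
        }


@dataclass
class CorrelationReport:
    metric: str
    provenance_a: str
    provenance_b: str
    pearson_r: float | None
    spearman_rho: float | None
    n_weeks: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "provenance_a": self.provenance_a,
            "provenance_b": self.provenance_b,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "n_weeks": self.n_weeks,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# sampling

def sample_same_size(
    source: BipartiteNetwork,
    n_plants: int,
    n_insects: int,
    rng: np.random.Generator,
    weight_mode: str = "continuous",
    max_attempts: int = 10000,
    discard_log: list | None = None,
) -> BipartiteNetwork:
    """One same-size random network drawn from ``source``.

    Species drawn uniformly without replacement; links are the induced
    subgraph of source links; weights ~ Uniform[min, max] of the source's
    positive weights (``weight_mode="discrete"`` resamples observed weight
    values instead). Species left isolated by the draw are kept, but a
    replicate with no links at all is discarded, logged, and redrawn.
    """
    if n_plants > source.n_plants or n_insects > source.n_insects:
        raise ValueError(
            f"requested {n_plants}x{n_insects} exceeds source "
            f"{source.n_plants}x{source.n_insects}"
        )
    if weight_mode not in ("continuous", "discrete"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    b = source.weights > 0
    pos = source.weights[b]
    wmin, wmax = float(pos.min()), float(pos.max())
    for _ in range(max_attempts):
        rows = rng.choice(source.n_plants, size=n_plants, replace=False)
        cols = rng.choice(source.n_insects, size=n_insects, replace=False)
        sub = b[np.ix_(rows, cols)]
        n_links = int(sub.sum())
        if n_links > 0:
            break
        if discard_log is not None:
            discard_log.append("all-empty replicate discarded")
    else:
        raise RuntimeError(
            f"{max_attempts} consecutive all-empty draws from source "
            f"{source.period!r} at size {n_plants}x{n_insects}"
        )
    weights = np.zeros(sub.shape)
    if weight_mode == "continuous":
        weights[sub] = rng.uniform(wmin, wmax, size=n_links)
    else:
        weights[sub] = rng.choice(pos, size=n_links, replace=True)
    return BipartiteNetwork(
        plants=[source.plants[r] for r in rows],
        insects=[source.insects[c] for c in cols],
        weights=weights,
        period=f"null:{source.period}",
        provenance=source.provenance,
    )


def empirical_quantiles(values: np.ndarray, lo: float = 0.025, hi: float = 0.975):
    """Order-statistic quantiles without interpolation (lower/higher)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    return float(v[int(np.floor(lo * (n - 1)))]), float(v[int(np.ceil(hi * (n - 1)))])


def _resolve_metric(metric, restarts: int, seed: int):
    if callable(metric):
        return metric
    if metric == "modularity_q":
        return lambda net: modularity(net, restarts=restarts, seed=seed)[0]
    try:
        return NULL_METRICS[metric]
    except KeyError:
        raise KeyError(f"unknown metric {metric!r}; known: {sorted(NULL_METRICS)}") from None


def null_distribution(
    observed: BipartiteNetwork,
    source: BipartiteNetwork,
    metric: str,
    R: int = 1000,
    seed: int = 0,
    weight_mode: str = "continuous",
    modularity_restarts: int = 5,
) -> NullDistribution:
    """Two-tailed quantile test of one observed metric against R same-size
    random draws from ``source``.

    Verdicts use strict comparisons: ``low`` iff observed < 0.025 quantile,
    ``high`` iff observed > 0.975 quantile, else ``ns``. Replicates on which
    the metric is undefined are excluded from the quantiles and counted.
    """
    func = _resolve_metric(metric, modularity_restarts, seed)
    rng = np.random.default_rng(seed)
    try:
        obs = float(func(observed.pruned()))
    except UndefinedMetric:
        return NullDistribution(
            metric=str(metric),
            source_label=source.period,
            observed=None,
            replicates=np.empty(0),
            q_low=None,
            q_high=None,
            verdict="undefined",
            seed=seed,
        )
    obs_pruned = observed.pruned()
    discards: list = []
    values = []
    n_undef = 0
    for _ in range(R):
        rep = sample_same_size(
            source,
            obs_pruned.n_plants,
            obs_pruned.n_insects,
            rng,
            weight_mode=weight_mode,
            max_attempts=10 * R,
            discard_log=discards,
        )
        try:
            values.append(float(func(rep.pruned())))
        except UndefinedMetric:
            n_undef += 1
    values = np.asarray(values)
    if len(values) == 0:
        verdict, q_low, q_high = "undefined", None, None
    else:
        q_low, q_high = empirical_quantiles(values)
        verdict = "low" if obs < q_low else "high" if obs > q_high else "ns"
    return NullDistribution(
        metric=str(metric),
        source_label=source.period,
        observed=obs,
        replicates=values,
        q_low=q_low,
        q_high=q_high,
        verdict=verdict,
        seed=seed,
        n_discarded_empty=len(discards),
        n_undefined=n_undef,
    )


def weekly_vs_annual(
    weekly: NetworkSeries,
    annual: BipartiteNetwork | dict[int, BipartiteNetwork],
    metrics: list[str],
    R: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One NullDistribution per (week, metric), with the week's own annual
    network as the resampling source. Weekly species must be a subset of the
    annual web's species."""
    rows = []
    seq = np.random.SeedSequence(seed)
    for (year, week), net in weekly:
        src = annual[year] if isinstance(annual, dict) else annual
        missing_p = sorted(set(net.plants) - set(src.plants))
        missing_i = sorted(set(net.insects) - set(src.insects))
        if missing_p or missing_i:
            raise ValueError(
                f"weekly network {year}-w{week} has species absent from its annual "
                f"source: plants {missing_p}, insects {missing_i}"
            )
        for metric in metrics:
            sub_seed = int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            nd = null_distribution(net, src, metric, R=R, seed=sub_seed)
            row = nd.to_dict()
            row.update({"year": year, "week": week})
            rows.append(row)
    return pd.DataFrame(rows)


def annual_vs_metaweb(
    annuals: dict[int, BipartiteNetwork],
    metaweb: BipartiteNetwork,
    metrics: list[str],
    R: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One NullDistribution per (year, metric), resampling from the metaweb."""
    rows = []
    seq = np.random.SeedSequence(seed)
    for year in sorted(annuals):
        for metric in metrics:
            sub_seed = int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            nd = null_distribution(annuals[year], metaweb, metric, R=R, seed=sub_seed)
            row = nd.to_dict()
            row.update({"year": year})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations between network types

def correlate_metrics(a: pd.DataFrame, b: pd.DataFrame, metric: str) -> CorrelationReport:
    """Pearson and Spearman correlation of one weekly metric between two
    network types, over weeks where both networks exist.

    ``a`` and ``b`` are weekly metric tables with ``year``, ``week``,
    ``provenance`` and metric columns (see :func:`pollinet.pipeline.metric_table`).
    """
    merged = a.merge(b, on=["year", "week"], suffixes=("_a", "_b"))
    xa = merged[f"{metric}_a"] if f"{metric}_a" in merged else merged[metric]
    xb = merged[f"{metric}_b"] if f"{metric}_b" in merged else merged[metric]
    pair = pd.DataFrame({"a": xa, "b": xb}).dropna()
    prov_a = a["provenance"].iloc[0] if len(a) else "?"
    prov_b = b["provenance"].iloc[0] if len(b) else "?"
    if len(pair) < 3:
        raise ValueError(f"need >= 3 shared weeks with defined {metric}, got {len(pair)}")
    if pair["a"].nunique() == 1 or pair["b"].nunique() == 1:
        return CorrelationReport(metric, prov_a, prov_b, None, None, len(pair), "zero variance")
    r = float(stats.pearsonr(pair["a"], pair["b"]).statistic)
    rho = float(stats.spearmanr(pair["a"], pair["b"]).statistic)
    return CorrelationReport(metric, prov_a, prov_b, r, rho, len(pair))


# ---------------------------------------------------------------------------
# calibration

def calibration_rejection_rate(
    source: BipartiteNetwork,
    n_plants: int,
    n_insects: int,
    R: int = 1000,
    n_trials: int = 1000,
    seed: int = 0,
    metric: str = "connectance_wt",
) -> float:
    """Self-calibration of the null test: rejection rate when the observed
    network is itself drawn by the null mechanism.

    For each trial, one "observed" and R replicate networks are drawn by the
    same law as :func:`sample_same_size` (vectorized in batches for speed,
    but identical in distribution), the metric is computed on each after
    pruning isolated species, and the strict two-tailed quantile verdict is
    applied. Returns the fraction of trials rejected; nominally ~5%.
    """
    if metric not in ("connectance_bin", "connectance_wt"):
        raise ValueError("calibration supports connectance_bin / connectance_wt")
    rng = np.random.default_rng(seed)
    b = (source.weights > 0).astype(float)
    pos = source.weights[source.weights > 0]
    wmin, wmax = float(pos.min()), float(pos.max())
    P, A = b.shape
    n_rej = 0
    batch = R + 1  # index 0 plays the observed network
    for _ in range(n_trials):
        vals = np.full(batch, np.nan)
        todo = np.arange(batch)
        while todo.size:
            # uniform subsets without replacement via random-key argpartition
            rsel = np.argpartition(rng.random((todo.size, P)), n_plants - 1, axis=1)[
                :, :n_plants
            ]
            csel = np.argpartition(rng.random((todo.size, A)), n_insects - 1, axis=1)[
                :, :n_insects
            ]
            sub = b[rsel[:, :, None], csel[:, None, :]]  # (t, n_p, n_i)
            n_links = sub.sum(axis=(1, 2))
            ok = n_links > 0
            idx_ok = todo[ok]
            sub_ok = sub[ok]
            if metric == "connectance_bin":
                p_eff = (sub_ok.sum(axis=2) > 0).sum(axis=1)
                a_eff = (sub_ok.sum(axis=1) > 0).sum(axis=1)
                vals[idx_ok] = n_links[ok] / (p_eff * a_eff)
            else:
                w = sub_ok * rng.uniform(wmin, wmax, size=sub_ok.shape)
                vals[idx_ok] = _weighted_connectance_batch(w)
            todo = todo[~ok]  # all-empty replicates redrawn
        q_low, q_high = empirical_quantiles(vals[1:])
        if vals[0] < q_low or vals[0] > q_high:
            n_rej += 1
    return n_rej / n_trials


def _weighted_connectance_batch(w: np.ndarray) -> np.ndarray:
    """Weighted connectance of a (t, P, A) weight stack, pruning isolated
    species per replicate (mirrors metrics.connectance_weighted)."""
    m = w.sum(axis=(1, 2))
    ld = np.zeros(len(w))
    for axis in (2, 1):
        marg = w.sum(axis=axis)  # (t, P) or (t, A)
        safe = np.where(marg > 0, marg, 1.0)
        p = w / (safe[:, :, None] if axis == 2 else safe[:, None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h = -plogp.sum(axis=axis)
        ld += 0.5 * (marg / m[:, None] * np.exp(h) * (marg > 0)).sum(axis=1)
    n_active = (w.sum(axis=2) > 0).sum(axis=1) + (w.sum(axis=1) > 0).sum(axis=1)
    return ld / n_active
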