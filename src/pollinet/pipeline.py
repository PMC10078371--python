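"""End-to-end analysis pipeline: records -> networks -> metrics -> nulls ->
pollination service, with deterministic, reproducible outputs.

One :class:`RunConfig` drives everything. All randomness flows from one
master seed through named substreams (generator, annual nulls, weekly
nulls, metric optimizer), so stages can be rerun independently and a rerun
with the same config reproduces every output file byte for byte (output
files carry no timestamps and use fixed float formatting).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import networks as nw
from . import records as rec
from . import service as sv
from .metrics import metric_set
from .nulls import annual_vs_metaweb, correlate_metrics, weekly_vs_annual
from .synth import generate, scenario

__all__ = ["RunConfig", "run", "metric_table", "svd_regressions"]

log = logging.getLogger(__name__)

CORRELATION_METRICS = ["n_plants", "n_insects", "n_links", "connectance_bin", "nodf_bin",
                       "modularity_q"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    scenario: str | None = "baseline"
    # file inputs (exactly one of scenario / input paths must be set)
    visits_path: str | None = None
    pollen_path: str | None = None
    svd_path: str | None = None
    taxonomy_path: str | None = None
    focal_plant: str | None = None  # default: synthetic dominant plant
    origin_month: int = 6
    origin_day: int = 1
    null_R: int = 1000
    null_metrics: tuple[str, ...] = ("connectance_bin", "nodf_bin", "n_links")
    modularity_restarts: int = 20
    exclude_insects: tuple[str, ...] = ()
    write_networks: bool = True

    def __post_init__(self) -> None:
        has_files = any([self.visits_path, self.pollen_path, self.svd_path])
        if bool(self.scenario) == has_files:
            raise ValueError("set exactly one of scenario / input paths")
        if has_files and not all(
            [self.visits_path, self.pollen_path, self.svd_path, self.taxonomy_path]
        ):
            raise ValueError("file input needs visits, pollen, svd and taxonomy paths")
        if has_files and not self.focal_plant:
            raise ValueError("focal_plant is required with file inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _substreams(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ["generator", "nulls_annual", "nulls_weekly", "modularity"]
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def metric_table(series_items, mode: str = "full", restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Weekly metric table: one row per network, keyed year/week."""
    rows = []
    for (year, week), net in series_items:
        ms = metric_set(net, mode=mode, restarts=restarts, seed=seed)
        row = ms.to_dict()
        row.update({"year": year, "week": week})
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("connectance_bin", "connectance_wt", "nodf_bin", "nodf_wt", "modularity_q"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def svd_regressions(svd_tab, pollen: pd.DataFrame, weekly_service: pd.DataFrame,
                    taxmap: rec.TaxonomyMap) -> dict[str, sv.RegressionResult]:
    """The two per-genus models: mean SVD against (a) mean total pollen
    carried per individual and (b) mean annual visits to the focal plant."""
    per_indiv = pollen.groupby(["insect", "individual"], as_index=False)["grains"].sum()
    per_indiv["genus"] = per_indiv["insect"].map(taxmap.genus_of)
    body = per_indiv.groupby("genus")["grains"].mean().rename("mean_body_load")

    svc = weekly_service.copy()
    svc["genus"] = svc["insect_taxon"].map(taxmap.genus_of)
    annual_visits = svc.groupby(["genus", "year"])["visits"].sum().reset_index()
    visits = annual_visits.groupby("genus")["visits"].mean().rename("mean_annual_visits")

    base = svd_tab.genus.set_index("genus")["mean"].rename("svd_mean")
    joined = pd.concat([base, body, visits], axis=1, join="inner").dropna()
    out = {}
    if len(joined) >= 3 and joined["mean_body_load"].nunique() > 1:
        out["svd_vs_body_load"] = sv.fit_line(joined["mean_body_load"], joined["svd_mean"])
    if len(joined) >= 3 and joined["mean_annual_visits"].nunique() > 1:
        out["svd_vs_visits"] = sv.fit_line(joined["mean_annual_visits"], joined["svd_mean"])
    return out


def run(config: RunConfig) -> dict:
    """Execute the full analysis; writes tables under ``config.out_dir`` and
    returns the in-memory results plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _substreams(config.seed)
    manifest: dict = {"seed": config.seed, "substream_seeds": seeds, "counts": {}}

    # --- stage 1: data ------------------------------------------------------
    if config.scenario:
        cfg = scenario(config.scenario, seed=seeds["generator"])
        visits, pollen, svd_obs, truth = generate(cfg)
        taxmap = truth.taxonomy
        focal = config.focal_plant or truth.dominant_plant
        reports = []
        manifest["scenario"] = config.scenario
        truth.to_json(out / "ground_truth.json")
    else:
        visits, rep_v = rec.read_records(config.visits_path, "visits")
        pollen, rep_p = rec.read_records(config.pollen_path, "pollen")
        svd_obs, rep_s = rec.read_records(config.svd_path, "svd")
        taxo, rep_t = rec.read_records(config.taxonomy_path, "taxonomy")
        taxmap = rec.TaxonomyMap.from_frame(taxo)
        focal = config.focal_plant
        reports = [rep_v, rep_p, rep_s, rep_t]
        truth = None
    for rep in reports:
        log.info(rep.summary())
    manifest["counts"]["visit_rows"] = int(len(visits))
    manifest["counts"]["pollen_rows"] = int(len(pollen))
    manifest["counts"]["svd_rows"] = int(len(svd_obs))
    manifest["counts"]["rejected_rows"] = int(sum(r.n_rejected for r in reports))

    # --- stage 2: harmonized records and networks ---------------------------
    inter = rec.visits_to_interactions(visits, config.origin_month, config.origin_day)
    inter = rec.harmonize(inter, taxmap, exclude_insects=config.exclude_insects)
    manifest["counts"]["interaction_records"] = int(len(inter))
    pollen_w = rec.pollen_assign_weeks(pollen, config.origin_month, config.origin_day)

    weekly_visit = nw.build_weekly_series(inter)
    weekly_combined = nw.NetworkSeries()
    for (year, week), net in weekly_visit:
        combined = nw.merge_pollen_links(
            nw.aggregate_plants_to_genus(net, taxmap), pollen_w, year=year, week=week,
            genus_map=taxmap,
        )
        weekly_combined.add(year, week, combined)
    weekly_pollen = nw.NetworkSeries()
    for (year, week), _ in weekly_visit:
        try:
            weekly_pollen.add(year, week, nw.pollen_transport_network(pollen_w, year, week))
        except nw.EmptyPeriodError:
            log.info("no pollen records in %s-w%s; pollen web skipped", year, week)

    years = weekly_visit.years()
    annual_visit = {
        y: nw.sum_networks([n for (yy, _), n in weekly_visit if yy == y], period=str(y))
        for y in years
    }
    annual_combined = {
        y: nw.sum_networks(
            [n for (yy, _), n in weekly_combined if yy == y], period=str(y),
            provenance="combined",
        )
        for y in years
    }
    metaweb = nw.build_metaweb(weekly_combined)

    # weeks observed in some year but empty in another are skipped, not zero
    all_weeks = sorted({w for _, w in weekly_visit.networks})
    skipped = [
        {"year": y, "week": w}
        for y in years
        for w in all_weeks
        if (y, w) not in weekly_visit
    ]
    manifest["skipped_weeks"] = skipped
    for s in skipped:
        log.info("week %(week)s of %(year)s has no records; skipped", s)

    if config.write_networks:
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for label, series in (
            ("visitation", weekly_visit),
            ("combined", weekly_combined),
            ("pollen", weekly_pollen),
        ):
            for (year, week), net in series:
                nw.write_edgelist(net, net_dir / f"{label}_{year}_w{week:02d}.csv")
        for y in years:
            nw.write_edgelist(annual_combined[y], net_dir / f"combined_{y}_annual.csv")
        nw.write_edgelist(metaweb, net_dir / "metaweb.csv")

    # --- stage 3: metrics ----------------------------------------------------
    mseed = seeds["modularity"]
    mrest = config.modularity_restarts
    tables = {
        "visitation": metric_table(weekly_visit, "full", mrest, mseed),
        "combined": metric_table(weekly_combined, "full", mrest, mseed),
        "pollen": metric_table(weekly_pollen, "binary_only", mrest, mseed),
    }
    annual_rows = []
    for y in years:
        for label, net in (("visitation", annual_visit[y]), ("combined", annual_combined[y])):
            ms = metric_set(net, "full", restarts=mrest, seed=mseed)
            row = ms.to_dict()
            row["year"] = y
            annual_rows.append(row)
    meta_ms = metric_set(metaweb, "full", restarts=mrest, seed=mseed)
    metrics_weekly = pd.concat(tables.values(), ignore_index=True)
    metrics_annual = pd.DataFrame(annual_rows)
    _write_csv(metrics_weekly, out / "metrics_weekly.csv")
    _write_csv(metrics_annual, out / "metrics_annual.csv")
    with open(out / "metrics_metaweb.json", "w", encoding="utf-8") as fh:
        json.dump(meta_ms.to_dict(), fh, indent=1, sort_keys=True)

    # --- stage 4: null models and correlations -------------------------------
    nulls_annual = annual_vs_metaweb(
        annual_combined, metaweb, list(config.null_metrics), R=config.null_R,
        seed=seeds["nulls_annual"],
    )
    nulls_weekly = weekly_vs_annual(
        weekly_combined, annual_combined, list(config.null_metrics), R=config.null_R,
        seed=seeds["nulls_weekly"],
    )
    _write_csv(nulls_annual, out / "nulls_annual.csv")
    _write_csv(nulls_weekly, out / "nulls_weekly.csv")

    corr_rows = []
    pairs = [("visitation", "combined"), ("visitation", "pollen"), ("combined", "pollen")]
    for a, b in pairs:
        for metric in CORRELATION_METRICS:
            try:
                rep = correlate_metrics(
                    tables[a][["year", "week", "provenance", metric]],
                    tables[b][["year", "week", "provenance", metric]],
                    metric,
                )
            except ValueError as err:
                log.info("correlation %s %s/%s skipped: %s", metric, a, b, err)
                continue
            corr_rows.append(rep.to_dict())
    correlations = pd.DataFrame(corr_rows)
    _write_csv(correlations, out / "correlations.csv")

    # --- stage 5: pollination service ----------------------------------------
    svd_tab = sv.svd_table(svd_obs)
    weekly_service = sv.estimate_service(weekly_visit, svd_tab, focal, taxmap=taxmap)
    annual = sv.annual_service(weekly_service)
    activity = sv.activity_periods(inter)
    transport = sv.estimate_transport(pollen_w)
    _write_csv(weekly_service, out / "service_weekly.csv")
    _write_csv(annual, out / "service_annual.csv")
    _write_csv(activity, out / "activity_periods.csv")
    _write_csv(transport, out / "transport_weekly.csv")

    regressions = {
        name: res.to_dict()
        for name, res in svd_regressions(svd_tab, pollen_w, weekly_service, taxmap).items()
    }
    try:
        regressions["service_vs_activity"] = sv.service_vs_activity(annual, activity).to_dict()
    except ValueError as err:
        log.info("service_vs_activity skipped: %s", err)
    with open(out / "regressions.json", "w", encoding="utf-8") as fh:
        json.dump(regressions, fh, indent=1, sort_keys=True)

    manifest["counts"].update(
        {
            "weekly_networks": len(weekly_visit),
            "weekly_pollen_networks": len(weekly_pollen),
            "years": years,
            "service_rows": int(len(weekly_service)),
            "transport_rows": int(len(transport)),
            "community_total_deposition": sv.community_total(weekly_service),
        }
    )
    manifest["metaweb"] = meta_ms.to_dict()
    manifest["svd_control_summary"] = svd_tab.control
    manifest["transport_rule"] = "estimated_removed = mean load per captured individual x n individuals"
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "manifest": manifest,
        "weekly_visit": weekly_visit,
        "weekly_combined": weekly_combined,
        "weekly_pollen": weekly_pollen,
        "annual_visit": annual_visit,
        "annual_combined": annual_combined,
        "metaweb": metaweb,
        "metrics_weekly": metrics_weekly,
        "metrics_annual": metrics_annual,
        "metrics_metaweb": meta_ms,
        "nulls_annual": nulls_annual,
        "nulls_weekly": nulls_weekly,
        "correlations": correlations,
        "svd_table": svd_tab,
        "service_weekly": weekly_service,
        "service_annual": annual,
        "activity": activity,
        "transport": transport,
        "regressions": regressions,
        "truth": truth,
    }
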