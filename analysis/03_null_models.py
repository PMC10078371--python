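#!/usr/bin/env python
"""Test observed network structure against metaweb-resampling nulls.

Compares each annual combined network to 1000 same-size draws from the
five-year metaweb, and each weekly network to draws from its annual web
(reduced replicate count here to keep the driver quick; the library default
is R=1000). Writes verdict tables and the cross-method metric correlations.
"""

import sys
from pathlib import Path

from pollinet import networks as nw
from pollinet import records as rec
from pollinet.nulls import annual_vs_metaweb, correlate_metrics, weekly_vs_annual
from pollinet.pipeline import CORRELATION_METRICS, metric_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
R = 1000
DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    visits, _ = rec.read_records(DATA / "visits.csv", "visits")
    pollen, _ = rec.read_records(DATA / "pollen.csv", "pollen")
    taxo, _ = rec.read_records(DATA / "taxonomy.csv", "taxonomy")
    taxmap = rec.TaxonomyMap.from_frame(taxo)
    inter = rec.harmonize(rec.visits_to_interactions(visits), taxmap)
    pollen_w = rec.pollen_assign_weeks(pollen)

    weekly = nw.build_weekly_series(inter)
    combined = nw.NetworkSeries()
    for (year, week), net in weekly:
        combined.add(year, week, nw.merge_pollen_links(
            nw.aggregate_plants_to_genus(net, taxmap), pollen_w, year=year, week=week,
            genus_map=taxmap))
    years = combined.years()
    annual = {
        y: nw.sum_networks([n for (yy, _), n in combined if yy == y], period=str(y),
                           provenance="combined")
        for y in years
    }
    metaweb = nw.build_metaweb(combined)

    ann_table = annual_vs_metaweb(annual, metaweb, ["connectance_bin", "nodf_bin", "n_links"],
                                  R=R, seed=SEED)
    wk_table = weekly_vs_annual(combined, annual, ["connectance_bin", "nodf_bin"],
                                R=200, seed=SEED + 1)
    ann_table.to_csv(OUT / "nulls_annual.csv", index=False, float_format="%.10g")
    wk_table.to_csv(OUT / "nulls_weekly.csv", index=False, float_format="%.10g")

    print("annual verdicts vs metaweb draws:")
    print(ann_table.groupby(["metric", "verdict"]).size().to_string())
    flagged = (wk_table["verdict"] != "ns").mean()
    print(f"weekly networks flagged nonrandom for {flagged:.0%} of (week, metric) tests")

    vis_table = metric_table(weekly, mode="full", restarts=5, seed=SEED)
    com_table = metric_table(combined, mode="full", restarts=5, seed=SEED)
    rows = []
    for metric in CORRELATION_METRICS:
        try:
            rows.append(correlate_metrics(
                vis_table[["year", "week", "provenance", metric]],
                com_table[["year", "week", "provenance", metric]], metric).to_dict())
        except ValueError:
            continue
    import pandas as pd

    corr = pd.DataFrame(rows)
    corr.to_csv(OUT / "correlations_visitation_combined.csv", index=False,
                float_format="%.10g")
    print("visitation vs combined weekly-metric correlations:")
    print(corr[["metric", "pearson_r", "spearman_rho"]].to_string(index=False))


if __name__ == "__main__":
    main()
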