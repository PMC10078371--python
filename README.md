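# pollinet

Temporal plant–pollinator network analysis and pollination-service
estimation for short-season visitation studies.

Ecologists monitoring pollination in strongly seasonal systems (high-Arctic
tundra, alpine meadows) collect three kinds of data: dated flower-visit
records, pollen loads washed from captured insects, and single-visit
deposition (SVD) trials counting the conspecific pollen grains one insect
visit leaves on a virgin stigma of a focal plant. `pollinet` turns those
tables into:

* **weekly, annual and metaweb bipartite networks** — visitation webs
  weighted by visit counts, pollen-transport webs, and combined webs in
  which each pollen-documented link conservatively adds one visit instance
  in its capture week;
* **structural metrics** per network: size, binary/weighted connectance
  (weighted via entropy-based linkage density, LD/(P+A)), binary/weighted
  NODF nestedness, and Barber's bipartite modularity
  Q = (1/m)Σ<sub>ij</sub>[w<sub>ij</sub> − s<sub>i</sub>t<sub>j</sub>/m]·δ(g<sub>i</sub>, g<sub>j</sub>)
  maximized by a seeded multi-restart search;
* **metaweb-resampling null models**: each observed web is compared with
  1000 same-size random draws from its source pool (species sampled
  uniformly, links induced from the source, weights ~ Uniform over the
  observed range), with strict two-tailed verdicts at the empirical
  0.025/0.975 quantiles, plus Pearson/Spearman correlations of weekly
  metrics between network types;
* **pollination-service estimates**: per taxon and week, visits to the
  focal plant × mean SVD (genus level, family fallback), with annual
  totals, pollen-transport totals, activity periods, and the stepwise
  deposition ~ activity-period regression.

Because studies of this kind rarely deposit their raw interaction tables,
the package ships a seeded synthetic community generator
(`pollinet.synth`) reproducing the structure the analysis assumes — 13-week
seasons, midseason-peaked phenology windows, one super-generalist plant
attracting ~97% of visits, skewed pollinator contributions, overdispersed
pollen loads — so every stage runs and is tested end-to-end without any
download. See `docs/methods.md` for models, parameters and limitations.

## Worked example

```sh
pollinet all --scenario baseline --seed 1 --out results/demo
```

```
done: 64 weekly networks, community total deposition 1.94e+06 grains -> results/demo
```

The run writes edge lists, metric tables, null-test verdicts, correlation
and service tables, regression JSON and a manifest. The same analysis as a
readable sequence of drivers:

```sh
python analysis/01_simulate.py 1            # write synthetic tables
python analysis/02_networks_and_metrics.py 1
python analysis/03_null_models.py 1
python analysis/04_pollination_service.py 1
```

which prints, for seed 1:

```
dominant plant (Plantgenus01) attracts 97.1% of visits
metaweb: 20 plants x 65 insects, 339 links, connectance 0.261, NODF 46.6, Q 0.216
mean weekly connectance, shoulder weeks: 0.482; midseason: 0.138
community-total deposition on Plantgenus01: 761,907 grains over 5 years
top contributors: Genus19 sp05 (189,098); Genus02 sp01 (83,431); Genus21 sp03 (71,998)
```

Reading: only ~a quarter of the possible metaweb links are ever realized;
weekly connectance is *lowest* midseason, when many co-active species share
few partners each, and highest in sparse shoulder weeks (a two-plant week
cannot fall below connectance 0.5, since every insect present must visit
one of them); and a handful of abundant, long-active taxa dominate the
estimated pollen deposition on the focal plant.

## Library use

```python
from pollinet import records, networks, metrics, nulls, service, synth

visits, pollen, svd, truth = synth.generate(synth.scenario("baseline", seed=1))
inter = records.harmonize(records.visits_to_interactions(visits), truth.taxonomy)
weekly = networks.build_weekly_series(inter)
meta = networks.build_metaweb(weekly)
print(metrics.metric_set(meta).to_dict())
```

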