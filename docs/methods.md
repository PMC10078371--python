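# Methods

`pollinet` analyses temporal plant–pollinator interaction data of the kind
collected in short-season (high-Arctic or alpine) visitation studies: dated
flower-visit records, pollen loads washed from captured insects, and
single-visit deposition (SVD) trials on virgin stigmas of a focal plant.
This note documents the models and procedures, the tunable parameters, what
the synthetic community does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Data model and week assignment

All tables are plain delimited text with fixed headers (see
`pollinet.records.SCHEMAS`). Records without a parseable date are rejected
at parse time and listed in the parse report — seasonal analyses cannot use
them, and imputation is out of scope. Duplicate (individual, plant genus)
pollen rows are treated as data corruption and refused rather than merged.

Weeks are 7-day bins counted from a fixed calendar origin (default June 1)
applied in each observation's own year, so week *w* denotes the same
calendar window in every year and weekly networks are comparable across
years. The origin and bin width are conventions; nothing downstream depends
on their specific values, only on their being fixed.

Taxon names are canonicalized through a total mapping (raw name →
canonical name, rank, family). Harmonization merges records made identical
by renaming: visit counts add; pollen-evidence links stay at count 1
(presence, not frequency). Harmonization is idempotent and conserves total
visit counts. Non-insect flower visitors (e.g. crab spiders, mites) can be
excluded by name at this stage.

## Network construction

A weekly (or annual) network contains exactly the species observed
interacting in that period; species present at the site but inactive in the
period are excluded, so phenologically forbidden links never inflate the
denominator of connectance. Visitation weights are summed visit counts.

Pollen loads add links conservatively: an insect carrying a plant genus's
pollen must have visited it at least once, but the load says nothing about
visit number, so each distinct (insect, genus) pair with a positive load
adds exactly **+1** to the link weight in the week the insect was captured
(pollen is assumed to reside briefly on the body; secondary transport is
ignored). Because pollen is genus-resolved, combined networks first
aggregate the plant side to genus. Annual combined networks apply the +1
rule per week and then sum, not +1 per year — the weekly dating of pollen
links makes this the consistent choice.

The metaweb is the union of all weekly networks; its weight for a link is
the number of weekly networks containing it (temporal frequency), with the
binary view used for structural metrics.

## Structural metrics

* **Binary connectance** L/(P·A) over species present in the period.
* **Weighted connectance** is entropy-based linkage density divided by
  (P+A): LD = ½[Σ_j (m_·j/m)e^{H_j} + Σ_i (m_i·/m)e^{H_i}], with H the
  natural-log Shannon entropy of a species' weight distribution, so e^H is
  its effective partner number. The back-transform makes the measure
  log-base invariant.
* **NODF** (binary): for every unordered species pair within a side,
  100 × |shared partners| / (fill of the poorer species) when the fills are
  strictly unequal, else 0; averaged over all row pairs and column pairs.
  Ties contribute zero, which makes the statistic invariant to row/column
  order without any global sorting step.
* **Weighted NODF**: a pair contributes only when the poorer species'
  *marginal total* is strictly smaller; it counts partners where the poorer
  weight is positive but strictly below the richer weight, again over the
  poorer fill. Note that some toolchains condition on decreasing *fill*
  instead of decreasing totals; the two conventions agree on matrices where
  the orderings coincide but are not identical in general. The
  strict-totals convention is used here and the test oracle enumerates it
  directly.
* **Modularity** is Barber's bipartite Q = (1/m)Σ_{p,i}[w_pi −
  s_p t_i/m]δ(g_p, g_i), maximized by a seeded multi-restart local search:
  random initial labellings (the first restart starts from singletons),
  greedy single-node moves (including moves into a fresh module) and
  pairwise module merges until no move improves Q, best of `restarts`
  (default 20) kept. The heuristic only ever evaluates valid partitions, so
  it can never exceed the exhaustive optimum; on webs with ≤ 9 species an
  exhaustive set-partition search (Bell(9) = 21 147 partitions) is used as
  the test oracle, and the heuristic matches it in ≥ 95% of random
  instances. Q values from stochastic optimizers are reproducible only
  under a fixed seed; no exact agreement with other software is claimed.

Pollen-transport networks are analysed with binary metrics only: their
weights (individuals carrying pollen) are a different currency from visit
counts, so weighted values would not be comparable across network types.
Undefined metrics (NODF on a web with both sides singleton, metrics on an
empty web) are reported as explicit missing values, never as 0.

## Null models

The resampling null asks whether an observed network is structurally
unusual *given the species pool and link repertoire of a larger web*. A
replicate drawn from a source web (metaweb for annual tests, the annual web
for weekly tests) keeps the observed numbers of plants and insects:

1. species are drawn uniformly without replacement from the source pools
   (the sampling law is the minimal assumption; the data give no species
   weights);
2. the link set is the induced subgraph of the source links, so link number
   varies naturally with the species drawn;
3. each present link's weight is drawn from continuous Uniform[min, max]
   of the source's positive weights (a discrete resample of observed values
   is available as `weight_mode="discrete"`).

Species left isolated by the draw are kept as drawn but pruned before
metric computation, exactly as observed networks are. A replicate with no
links at all is discarded, logged and redrawn (metrics are undefined on an
empty graph); more than 10·R consecutive empty draws abort with a
diagnostic. Significance uses empirical order-statistic quantiles without
interpolation (lower/higher) and strict inequalities: verdict `low` iff
observed < q0.025, `high` iff observed > q0.975. Under self-calibration
(observed drawn by the same mechanism, R = 1000) the two-tailed rejection
rate is ~5%; the calibration harness evaluates weighted connectance because
it is continuous — discrete metrics (binary connectance, link counts) tie
with their quantiles and make the strict test conservative.

Cross-method agreement between network types is summarized by Pearson and
Spearman correlations (average ranks for ties) of weekly metric series over
the weeks where both networks exist; fewer than 3 shared weeks is an error
and zero variance is flagged rather than returned as a coefficient.

## Pollination service

SVD means are computed per insect genus; where a visiting taxon's genus has
no trials, the family mean is used (family means pool *all* trials of the
family, including genus-resolved ones — the inclusive choice uses every
observation). Taxa with neither level are excluded and logged; there is no
global-mean fallback. Control-flower (unvisited stigma) deposition is
summarized alongside but never subtracted from SVD means.

Weekly deposition per taxon = visits to the focal plant that week × SVD
mean; annual totals are exact sums of weekly rows, and the community total
sums over taxa with SVD data. The estimator is linear in visits by
construction.

Pollen transport per (taxon, plant, week) uses the mean load over the
taxon's captured individuals that week (individuals captured without that
pollen count as zeros) scaled by the number of individuals captured —
equivalently, the raw grain total for the group. Per-individual scaling is
a documented convention (recorded in the run manifest); per-visit scaling
would require knowing how many visits produced a load, which the data do
not contain.

Activity period of a taxon = mean over years (in which it was observed at
all) of the number of distinct weeks with observations.

Simple regressions (`fit_line`) are OLS from the normal equations with the
two-sided t test (df = n−2) for the slope; both multiple and adjusted R²
are reported, and a negative adjusted R² is reported as-is. The deposition
model starts from deposition ~ activity·year (year centered, continuous)
and drops nonsignificant terms at p > 0.05 stepwise — interaction first,
then the year main effect — leaving an activity-only model when both drop;
the year main effect is only considered for dropping after the interaction
is gone.

## Synthetic community

The generator emulates the statistical structure such a study assumes,
without claiming to match any real site's parameters:

| parameter | default | role |
|---|---|---|
| n_years / weeks_per_season | 5 / 13 | short snow-free seasons |
| n_plants / n_insects | 20 / 65 | community sizes |
| dominant_plant_visit_share | 0.97 | super-generalist plant's expected share of visits |
| plant/insect window centers | Normal(midseason, 2 wk) | unimodal midseason richness |
| window widths | LogNormal(log 6 / log 4, 0.4 / 0.5), clipped ≥ 1 wk | few long-active taxa |
| attract / abundance sdlog | 0.8 / 1.0 | skewed visit contributions |
| visit_rate_scale | 0.05 | visits per allowed pair-week |
| link_prob | 0.3 | repertoire (allowed links) density |
| pollen_nb_size | 0.5 | overdispersion of body loads |
| svd_mean_range | (5, 400), log-uniform | true per-genus deposition |
| svd_n_per_genus / svd_nb_size | 30 / 3 | trial design and noise |
| control mixture | 0.74·Poisson(2) + 0.26·NB(64, 0.8) | contamination: median 2, mean ≈ 19, SD ≈ 46 |

Visit counts are Poisson with rate ∝ attractiveness × abundance ×
phenological overlap over the allowed-link repertoire; the dominant plant's
weekly rate is set to share/(1−share) times the other plants' total that
week, split over active insects by abundance, so its expected share equals
the configured value each week. Scenario presets: `baseline` (=
`no_year_effect`; rates are identical across years by construction),
`strong_activity_effect` (wider spread of activity widths, damped abundance
and SVD variation, so annual deposition is dominated by activity length),
and `midseason_specialists` (midseason-active insects restricted to ≤ 2
non-dominant partners, higher realization rates, so weekly connectance dips
midseason while richness peaks there).

What the generator does **not** emulate: observation-effort variation and
weather gaps, taxonomic mis-identification, year effects and phenological
trends, secondary pollen transport, heterospecific deposition, and spatial
structure. Passing tests therefore show that the estimators recover the
generating process under idealized sampling, not that they are robust to
those field realities.

Everything derives from one `numpy` Generator seeded from the config; the
same config and seed reproduce all tables bit for bit. In the pipeline, a
master seed spawns named substreams (generator, annual nulls, weekly nulls,
modularity), outputs carry no timestamps and use fixed float formatting, so
a rerun is byte-identical.

## Statistical character of the recovery checks

Several guarantees are intrinsically statistical and are tested as such:
each per-genus SVD mean lies within 2 SE of truth with ~95% probability
(the suite asserts ≥ 85% coverage over ~25 genera); the community-total
deposition error concentrates on a few high-abundance genera and has a
relative-error SD of several percent at the default trial design
(CV of a genus mean ≈ √((1/n)(1/μ + 1/k)) ≈ 10% at n = 30, NB size k = 3),
so the suite asserts the *median* error over ten seeded studies is below
10%; and the null-model self-calibration rate is checked against the 99%
binomial band around the nominal 5%.

## Problem sizes

Default problem sizes used by the test suite and the acceptance script —
all chosen as the package's own study conditions: 5-year, 13-week baseline
community (~1.5–2k visit rows, ~2.5k pollen rows); NODF oracle on 1000
random 6×6 webs; modularity oracle on 50 webs of ≤ 9 species; calibration
at 1000 trials × R = 1000 (vectorized batch path, identical sampling law);
containment over 10 000 draws; 20 seeded runs for the seasonal pattern.
Driver scripts use R = 1000 for annual nulls and R = 200 for the ~60 weekly
tests.

## Known limitations

* The modularity optimizer is a heuristic; for webs much larger than a few
  hundred species its greedy moves may need more restarts than the default.
* The uniform species-sampling law in the null is an assumption; abundance-
  weighted sampling would be a natural extension.
* Week binning ignores partial observation weeks at season edges.
* Family-level SVD fallback inherits the family's genus composition bias;
  the `svd_level` column flags affected estimates.
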