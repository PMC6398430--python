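# crowflock

Fission–fusion analysis of partially marked bird populations: mark-resight
local flock size estimation, residency classification from sighting
histories, spatial subgroup detection, seasonal resampling inference, and
all-subsets Akaike-weighted model averaging of environmental effects — with
an agent-based synthetic sighting generator for end-to-end validation.

## The scientific problem

Free-ranging corvid flocks at a shared foraging site change size and
composition continuously: some birds reside on site, others visit
continuously, periodically, or only rarely, and foraging aggregations form
and dissolve within a day. Quantifying these fission–fusion dynamics from
transect scan data poses four linked problems, each handled by one module:

1. **How many birds use the site each day?** Only a fraction of the
   population is colour-ringed; unmarked birds cannot be told apart, so
   repeated sightings inflate raw counts. The within-day resighting ratio
   of the *marked* birds provides a correction factor

   $$\mathrm{CF} = \frac{CM_t - CM_{ind}}{CM_t}$$

   where $CM_t$ is the total number of marked-bird sightings on a day and
   $CM_{ind}$ the number of unique marked individuals. The daily local
   flock size estimate is

   $$FS_e = CM_{ind} + \frac{CU - CU \cdot \mathrm{CF}}{T}$$

   with $CU$ the unmarked sighting total and $T$ the number of transects
   that day (effort division applies only to the unmarked term). A
   per-transect variant $CM_{ind,t} + CU_t(1-\mathrm{CF})$ feeds the count
   models. With more than one transect per day this estimator is a
   deliberate *conservative minimum* of the true flock size (see
   `docs/methods.md` for the closed-form bias). (`crowflock.flock`)

2. **Who uses the site, and how?** Each identified marked bird yields
   three sighting-history features — days seen, longest gap without
   observation, and the SD of gap lengths, all in monitoring days.
   Complete-linkage agglomerative clustering of the z-scored features
   partitions birds seen on ≥ 5 days into *resident*, *continuous* and
   *periodic* presence categories; birds below the cutoff are *rare*
   visitors a priori. (`crowflock.presence`)

3. **Who forages with whom?** A foraging subgroup is a maximal chain of
   nonflying birds in which every member has a neighbour within 5 m with
   an unobstructed line of sight; subgroups are connected components of
   that association graph, with walls and tree lines as sight barriers.
   (`crowflock.subgroups`)

4. **What drives flock and subgroup size?** Daily category proportions
   are compared across breeding (Feb–May), parental care (Jun–Sep) and
   nonbreeder (Oct–Jan) seasons with a bootstrap Friedman / paired
   Wilcoxon battery, per-bird relative presence with permutation Friedman
   and exact signed-rank tests, and subgroup sizes across categories with
   Kruskal–Wallis and Mann–Whitney post hocs (`crowflock.seasons`).
   Environmental effects are estimated by fitting *every* subset of a
   candidate term set as a log-link count model with a date-level random
   intercept (32 models for flock size, 1024 for subgroup size), weighting
   models by $w_i \propto e^{-\Delta_i/2}$ ($\Delta_i$ = AIC difference to
   the best model) and forming the full (zero-substitution) weighted
   average of every coefficient with its unconditional SE
   (`crowflock.modelavg`, GLMM engine in `crowflock.glmm`).

The synthetic generator (`crowflock.synthetic`) simulates the whole data
process — residency archetypes, seasonal presence shifts, transect
detection, and covariate-driven spatial grouping — and emits the ground
truth alongside, so every estimator above is validated against known
answers.

## Worked example

```python
from crowflock.synthetic import simulate_study
from crowflock.flock import daily_series
from crowflock.presence import feature_table, assign_categories
from crowflock.subgroups import subgroup_table

sim = simulate_study(seed=1)                      # one year, 322 marked birds
daily = daily_series(sim["records"])
print(f"monitoring days: {len(daily)}")
print(f"mean correction factor: {daily['CF'].mean():.3f}")
print(f"mean daily flock estimate: {daily['FS_e'].mean():.1f} "
      f"+/- {daily['FS_e'].std(ddof=1):.1f} birds")

features = feature_table(sim["records"])
assignments = assign_categories(features, min_days=5, k=3)
print("presence categories:", assignments["category"].value_counts().to_dict())

groups = subgroup_table(sim["records"], barriers=sim["world"].barriers)
sizes = groups.drop_duplicates("subgroup_id")["subgroup_size"]
print(f"subgroups: {len(sizes)}, mean size {sizes.mean():.2f}, largest {sizes.max()}")
```

prints

```
monitoring days: 130
mean correction factor: 0.172
mean daily flock estimate: 70.5 +/- 11.2 birds
presence categories: {'continuous': 45, 'resident': 38, 'rare': 28, 'periodic': 8}
subgroups: 11090, mean size 1.82, largest 13
```

About 17% of marked sightings within a day are resightings, so roughly one
in six unmarked sightings is discounted; the site hosts ~70 birds on a
typical day; and most foraging subgroups are singletons or pairs with a
heavy right tail — the size and shape of structure the method is built to
measure.

The same stages are available from the shell:

```bash
crowflock run --out run/ --seed 1          # full pipeline into run/
crowflock estimate --sightings run/sightings.csv --out daily.csv
crowflock classify --sightings run/sightings.csv
crowflock subgroups --sightings run/sightings.csv --world run/world.yaml
crowflock summarize --sightings run/sightings.csv --marked-total 322
```

Every run directory contains per-stage provenance records (config hash,
seed, version); a rerun with the same configuration is byte-identical.

## Layout

| Module | Contents |
| --- | --- |
| `crowflock.synthetic` | world/agent configs, presence + transect simulation |
| `crowflock.flock` | correction factor, daily and per-transect estimates |
| `crowflock.presence` | gap features, clustering, category assignment |
| `crowflock.subgroups` | association graph, components, subgroup tables |
| `crowflock.seasons` | season partition, bootstrap/permutation/exact tests |
| `crowflock.glmm` | Laplace Poisson/NB regression with date random intercept |
| `crowflock.modelavg` | design encoding, all-subsets fits, model averaging |
| `crowflock.pipeline` | stage orchestration, provenance, population summary |
| `crowflock.cli` | `crowflock` command group |

`docs/methods.md` documents the models, their assumptions, parameter
defaults, numerical choices, and known limitations.
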