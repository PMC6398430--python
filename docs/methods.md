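# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic validation does and does not demonstrate.

## Mark-resight flock size estimation

**Model.** On each monitoring day a partially marked population is
surveyed by `T` transect scans. Marked birds are individually
identifiable, so their within-day resighting ratio
`CF = (CM_t − CM_ind)/CM_t` measures how often a bird present that day is
recorded more than once. Unmarked sighting totals `CU` are deflated by the
same ratio, on the assumption that marked and unmarked birds share the
presence and detection process. The daily estimate is
`FS_e = CM_ind + (CU − CU·CF)/T`; the marked term needs no effort division
because unique marked individuals are known exactly.

**Bias structure.** Write `d` for the per-session detection probability
and `a = 1 − (1−d)^T` for the probability a present bird is recorded at
least once in a day. For any generative model in which marked and
unmarked birds are detected identically, the unmarked term reduces
algebraically to `U·a/T`, so

```
E[FS_e] ≈ a · (M + U/T)
```

for `M` marked and `U` unmarked birds present. The estimator is therefore
a *conservative minimum* whenever `T > 1`: the effort division suppresses
the unmarked contribution by roughly `1/T` on top of the detection loss.
This is a property of the estimator, not a defect of the implementation;
a unit test verifies the closed form at `T = 2`. Consequently, unbiased
recovery of the true flock size is validated in the single-transect
regime (`sessions_per_day = 1`, detection 0.95), where the measured mean
relative error is about −5% (the detection loss), well inside the ±10%
validation band. Multi-transect estimates should be read as lower bounds
and compared only with estimates at equal effort.

**Degenerate days.** Days with unmarked sightings but no identified
marked sightings have an undefined CF; the study-period mean CF is
substituted and the day flagged (`cf_imputed`), keeping the daily series
complete. Marked birds whose ring could not be read carry no resighting
information and are tallied with the unmarked sightings — they are real
birds whose duplicate status is unknown, and dropping them would bias the
abundance low.

## Residency classification

**Features.** For each identified marked bird: `days_seen`, `max_gap`,
and `gap_sd`, where gaps are runs of *monitoring* days (days with at
least one transect) without an observation, between the bird's first and
last sighting. Monitoring days, not calendar days, because absence is
observable only when observers were present; otherwise every survey
interruption would inflate every bird's gaps in lockstep. Censored
leading/trailing intervals are excluded by default (a bird ringed
mid-study has not been "absent" before its first sighting);
`include_censored=True` gives the alternative reading. `gap_sd` uses the
sample (n−1) SD and is 0 with fewer than two gaps.

**Clustering.** Birds seen on ≥ `min_days` (default 5) days are clustered
by complete-linkage agglomeration on Euclidean distances between z-scored
features, cut at `k = 3`; birds below the cutoff are rare visitors a
priori. `k` is a parameter, not estimated: cluster number selection from
dendrogram shape is inherently judgement-laden, and the three-plus-rare
structure is the biological hypothesis under test. Clusters map to names
deterministically — descending mean `days_seen`, ties by ascending mean
`max_gap` — giving resident, then continuous, then periodic. Distance
ties inside the linkage resolve by scipy's lowest-index rule, so results
are reproducible for a fixed row order; a brute-force agglomeration
oracle checks the merges on small inputs.

## Subgroup detection

A subgroup is a connected component of the graph whose vertices are a
session's nonflying sightings and whose edges join pairs at Euclidean
distance ≤ 5 m (boundary inclusive) with a line of sight crossing no
barrier. Barrier obstruction uses open-segment semantics: a proper
interior crossing blocks, grazing an endpoint does not (zero-measure
contact), and collinear overlap of positive length blocks. Components are
computed per session and never span scans. The per-record table repeats
each subgroup's size once per member — the size-biased, per-observation
form the downstream models consume — while `drop_duplicates("subgroup_id")`
gives the per-group view. An independent orientation-test geometry plus
boolean transitive closure serves as the oracle.

## Seasonal inference

Seasons follow breeding ecology: breeding Feb–May, parental care Jun–Sep,
nonbreeder Oct–Jan, by calendar month.

**Bootstrap battery.** Daily category proportions are not naturally
paired across seasons, so each bootstrap iteration draws `sample_size`
(default 38) day-triplets — one day per season, with replacement, paired
by draw index — and computes the Friedman chi-square across the three
season columns, or the paired Wilcoxon signed-rank V (reported as V+, the
R convention) for each season pair. Results report the mean ± SE of the
statistic and of the p-value over iterations (default 10,000).

**Significance rule.** Averaging p-values over resamples is strongly
conservative as a decision rule: under the null a small p is pulled up by
resampling noise far more often than a large one is pulled down (measured
type-I error ~0.003–0.011 at nominal 0.05). The significance flag is
therefore derived from the resampling-mean *statistic* against its
reference distribution (`p_calibrated`: chi-square with k−1 df for
Friedman, normal for the mean signed-rank z). Measured type-I error of
this rule under exchangeable nulls is 0.03–0.07 across independent
replications. The mean p is still reported descriptively next to it.

**Other tests.** Per-bird relative days seen (days seen / monitoring days
per season) are compared with a within-block permutation Friedman test
(`p = (1 + #{χ²_perm ≥ χ²_obs})/(1 + n_resamples)`; an exhaustive
enumeration oracle validates it at 4 blocks) and exact paired signed-rank
tests (zeros dropped by Wilcoxon's rule; exact null when the remaining
differences are tie-free, tie-corrected normal approximation otherwise).
Subgroup sizes across categories use Kruskal–Wallis with tie correction
and all pairwise two-sided Mann–Whitney U tests. Bonferroni levels:
0.017 for the three season pairs, 0.008 for the six category pairs.

## Count models and model averaging

**Families and responses.** The per-transect flock size estimate, rounded
to the nearest integer, is modelled as Poisson; the subgroup size minus
one (singletons map to zero) as Poisson or NB2. Both use a log link and a
Gaussian random intercept on observation date, absorbing day-level
presence fluctuations shared by all of a day's records.

**Estimation.** statsmodels provides the fixed-effects-only fits. The
random-intercept fits use the package's own Laplace engine: with one
scalar random effect per group the marginal likelihood factorizes over
groups, each group's mode is found by a one-dimensional Newton iteration
(vectorized over groups via segment sums), and the Laplace-approximated
marginal log-likelihood is maximized over fixed effects, log RE-SD, and
log NB dispersion by L-BFGS-B. Box bounds let vanishing dispersion or RE
variance terminate cleanly at the boundary; boundary parameters are held
fixed when the curvature-based SEs are computed. The fits match
lme4::glmer (Poisson) and glmmTMB (nbinom2) to ~4 decimals on frozen
reference fixtures. AIC counts all estimated parameters (fixed effects +
log σ + log α where present).

**Averaging.** All `2^k` term subsets are fitted (32 flock, 1024
subgroup); nonconverged fits are dropped with a log message and the
Akaike weights renormalized. Weights are computed with max-subtraction
for overflow safety. The full (zero-substitution) average assigns a term
estimate 0 with SE 0 in every model omitting it; the unconditional SE is
`sqrt(Σ w_i (SE_i² + (b_i − b̄)²))` and a two-sided normal p-value is
derived from `b̄/SE`. AIC rather than AICc is the default; categorical
reference levels are Morning, nonbreeder season, cold, rain, few
visitors, in-forest, on-building, juvenile, and grass, with the numeric
crows-present covariate centred.

**Validated recovery.** Grouping effects injected by the generator are
recovered by the 16-model Poisson average within ±3 unconditional SE on
~6,000 subgroups (worst-case |z| ≈ 1.3). The recovery fit uses one row
per unique subgroup: per-record (size-biased) rows shrink log-linear
coefficients by the factor `1 − μ/((2+μ)(1+μ))` under the generator's
1+Poisson(μ) group-size law, so per-record fits are validated for sign
and ordering rather than magnitude.

## The synthetic generator

**What it emulates.** A ~13-month study window with transects every third
day (130 monitoring days), two scans per winter day and three per summer
day; 322 marked birds of which roughly a third are ever resighted; a
larger unmarked pool (default 1400) drawn from the same presence and
detection process; an 86.2% ring-identification rate; four residency
archetypes (resident: daily Bernoulli p=0.80; continuous: p=0.30;
periodic: alternating on/off blocks with shifted-Poisson lengths, means
21/35 days; rare: expected 0.65 presence days spread uniformly, which is
what keeps most of the marked pool unseen); multiplicative seasonal
presence modifiers; and foraging groups of size one plus a negative
binomial count (dispersion 1.0) whose log mean is linear in zone
attributes and session covariates. Group members are jittered within
2.5 m of foraging points kept ≥ 15 m apart, so the 5 m chain rule
recovers generated groups essentially exactly. Defaults reproduce the
intended structure: daily estimate ≈ 62–70 with about two-thirds
unmarked, mean CF ≈ 0.17–0.18, subgroup means ≈ 1.8 overall and ≈ 2.8 for
groups of two or more.

**Block-length law.** Periodic on/off blocks use shifted-Poisson rather
than geometric lengths. Geometric blocks make the periodic archetype's
realized (days-seen, max-gap) cloud span several standard deviations —
some periodic birds never lose an off-block to the window and look
resident, others look rare — and complete linkage then reliably splits
the periodic cloud while merging residents with continuous visitors,
making archetype recovery impossible (~0.45 agreement under every
parameterization tried). Concentrated block lengths preserve the
qualitative on/off signature while keeping the archetype identifiable.

**Validation scenarios.** Three frozen configurations back the
validation suite: `estimator_validation_configs` (single transect,
detection 0.95 — the regime where the estimator targets the truth),
`archetype_validation_configs` (80 birds from well-separated archetypes;
mean recovery agreement 0.91 over 20 seeds, residual errors being
boundary birds whose realized histories genuinely resemble the other
class), and `effect_recovery_configs` (a two-month always-present
population with Poisson group sizes and known injected effects).

**What passing does not show.** The generator's birds have no movement
within a session, no social preferences, no territory structure, and no
dependence between presence and detection; covariates act exactly
log-linearly. Passing recovery tests therefore demonstrates that the
estimators invert the generator's data process correctly — not that real
crows satisfy these assumptions. In particular the mark-resight
estimator's core assumption (equal marked/unmarked detection) is imposed
by construction here and must be argued ecologically in any field
application.

## Numerical choices

- Linkage distance ties: scipy's lowest-index merge rule (deterministic
  for fixed row order); constant features dropped from standardization
  with a warning.
- Permutation p-values use the add-one convention; the ≥ comparison
  carries a 1e-12 slack against float ties.
- GLMM inner Newton: ≤ 40 steps, step tolerance 1e-10; linear predictors
  clipped at ±30; warm-started group modes reset when they exceed ±20.
  Warm starts (full-model coefficients for submodels, carried group
  modes across objective evaluations) only accelerate convergence — a
  cold-start retry guards against a stranded line search.
- Duplicate sighting rows (same date, session, bird, position) are
  dropped before estimation; re-running any stage with identical inputs
  is byte-identical.
- Per-stage seeds derive from the global seed by SHA-256 of
  `"{seed}:{stage}"`, keeping stages independently reproducible.

## Problem sizes

Default analyses run on one CPU in seconds to a few minutes: the default
synthetic study produces ~22,000 sighting records; the season battery
uses 10,000 bootstrap iterations; the flock average fits 32
random-intercept Poisson models and the default pipeline subgroup average
32 NB models (the full 1024-model set is available by listing all ten
candidate terms in the run configuration); calibration checks use 1,000
outer replicates with 100 inner iterations. The acceptance script runs
the complete battery in under two minutes.

## Known limitations

- The estimator's conservative bias at `T > 1` means daily estimates are
  comparable only at equal transect effort; no detection-probability or
  capture–recapture model is fitted by design.
- Cluster number `k` is fixed, not selected; categories are constructs
  on a residency continuum, and boundary birds are genuinely ambiguous.
- The bootstrap pairing of days across seasons by draw index is an
  interpretation (days have no natural cross-season pairing); the exact
  resampling unit behind the original battery is underdetermined.
- The per-transect estimator uses `CU_t·(1 − CF_day)`; the alternative
  reading `CU_t·CF_day` is inconsistent with the daily estimator's
  structure and was not implemented.
- The 10-term subgroup candidate set (1024 models) is the configurable
  default surface; enumeration is exact but fitting all 1024
  random-intercept NB models is minutes of compute, so the default run
  configuration uses a 5-term subset.
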