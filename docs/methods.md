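# Methods

This note documents the models and procedures implemented by
`engagement_profiles`, the parameters that matter, what the synthetic data
do and do not emulate, and the design choices made where the design was
genuinely open.

## Daily activity categorization

Each user-day carries 13 raw metrics: four therapy-related (steps started,
actions done, visited suggested content, visited therapy home) and nine
social-networking-related (newsfeed posts/comments, problem-solving-forum
posts, likes, reactions, and visits to messages, notifications, newsfeed
and the forum). These are mapped to one ordinal level per dimension:

* **Therapy** — level 4 if `steps > 1` or `actions > 1` or
  (`steps ≥ 1` and `actions ≥ 1`); level 3 if exactly one step *xor* one
  action (one unit of activity total); level 2 if only therapy-side page
  visits; level 1 otherwise.
* **Social** — level 4 if any post/comment/forum contribution; level 3 if
  no contribution but ≥ 1 like or reaction; level 2 if only social-side
  page visits; level 1 otherwise.

The hierarchy is evaluated top-down, so overlapping descriptions resolve to
the highest applicable level (e.g. one step *and* one action is level 4,
not level 3). Choices that the published category descriptions leave open,
fixed here as conventions: visited-messages and visited-notifications count
as passive *social* visits (they concern network communication);
visited-suggested-content counts as passive *therapy*; the numeric
anchoring inactive=1 … highly-engaged/active=4 follows the two printed
anchors (passive=2, engaged=3).

## Weekly trajectories

Weeks are fixed 7-day blocks anchored at each user's day 2 (per-user
relative time, not calendar weeks). Day 1 is a supervised platform
induction and never contributes. The default window, days 2–155, spans 154
days = 22 complete weeks; the weekly score per dimension is the **maximum**
daily level in the block, reflecting the fortnightly-use adherence
expectation that motivated weekly granularity. Days with no log row count
as level 1 — absence of a row means no platform contact, not missing data —
so every user yields a complete 2 × 22 matrix and users with no
post-induction activity appear as all-ones trajectories (they are retained
and reported, mirroring how real cohorts contain enrolled non-users).

## Joint-trajectory K-means

Distance between users is plain Euclidean distance on the flattened
44-vector. Both dimensions share the same 1–4 ordinal scale, so no
normalization or dimension weighting is applied, and ordinal scores are
treated as numeric for centroid means — the convention of the kml3d family
of longitudinal K-means tools this component follows.

Each fit runs `n_restarts` (default 100) Lloyd iterations to label
convergence, cycling evenly through three initialization schemes (random
partition, K sampled users, greedy farthest-first seeding), keeping the
restart with minimal within-cluster inertia. Within a restart the inertia
sequence is non-increasing by construction. Empty clusters are repaired by
reseeding with the point farthest from its current centroid, keeping K
fixed. With 82 users the 100-restart minimum is reached many times over;
`best_of` records the restart count.

**Model selection** over K = 2…4 combines:

* Calinski–Harabasz `CH = [B/(K−1)] / [W/(n−K)]` (higher better),
* Ray–Turi = mean within-cluster squared distance / minimum squared
  inter-centroid distance (lower better),
* Davies–Bouldin = mean over clusters of `max_j (s_i+s_j)/d(c_i,c_j)` with
  `s` the mean member–centroid distance (lower better),

an exclusion rule (any cluster with fewer than `min_cluster_size`
members — default 15 — excludes that K), and a majority vote: each index
nominates its best admissible K; ties break by higher mean stability Rand
index. The procedure never overrides silently — if every K is excluded it
says so — and a user can force a K by pinning the candidate range. This
matters in practice: on cohorts shaped like the reference study (a large
low-use cluster plus two closer "maintained" clusters, smallest profile
≈ 14/82), all three indices genuinely favour K = 2 and the 14-member
solution sits below the 15-member floor, so the 3-profile solution is a
deliberate, documented override rather than an automatic choice.

**Stability** draws `n_resamples` (default 100) subsamples of 80% of users
without replacement, reclusters each, and scores the plain Rand index
between the resample partition and the full-data partition restricted to
the drawn users (adjusted Rand is logged alongside). Whether the reference
analysis resampled with or without replacement, and whether its Rand was
adjusted, is unstated; subsampling + raw Rand is this package's choice.

## Mixed models for treatment outcomes

For each outcome, long-format data (two timepoints) are fitted with

    value ~ group + time + group:time + sex + age + log(DUP) + (1 | user)

by REML via `statsmodels.MixedLM`. Group and time enter with sum-to-zero
coding so the reported F tests are the standard Type-III hypotheses. Time
is categorical with baseline as one of the two cells (cell-means style);
the model thereby "controls for baseline" through the baseline cells and
the within-user intercept. An ANCOVA-style variant (6-month value on group
plus baseline value) is available behind `baseline_covariate=True`, since
the phrase "controlled for baseline differences" admits both readings; the
cell-means parameterization is the default because the reference tables
report model-implied baseline and 6-month means.

Denominator degrees of freedom use a Satterthwaite-type approximation
computed in closed form for the random-intercept covariance
`V = σ²I + τ²ZZᵀ`: for a contrast `l`, `ν = 2(lᵀCl)²/Var(lᵀCl)` with
`C = (XᵀV⁻¹X)⁻¹`, the variance obtained by the delta method from the REML
information of (σ², τ²); multi-row tests use the eigencontrast-averaging
construction. statsmodels does not expose denominator df for `MixedLM`, so
this machinery is part of the package. In the balanced two-timepoint case
the group × time F reproduces the exact one-way ANOVA on user change
scores (a test asserts this), and simulation at the reference profile
sizes (49/19/14) shows type-I error ≈ 0.05 and 95% CI coverage ≈ 94–95%.

Post-hoc contrasts (change within one group; pairwise group differences at
one timepoint) are single-df Wald F tests from the same fitted covariance;
the within-group change contrast equals the difference of the two
model-implied cell means by construction. Boundary fits (τ̂² ≈ 0) are
flagged `singular`, not failed; rows with missing covariates are dropped
and counted. No multiple-testing correction is applied across outcomes by
default — every report carries an explicit caveat, matching the reference
analysis's acknowledged limitation — with optional Benjamini–Hochberg.

Baseline characterization uses one-way ANOVA (with a summary-statistic
variant `anova_from_summary` for published-table inputs), chi-square tests
for categorical variables, and Tukey HSD pairwise contrasts only when the
omnibus test is significant.

## Synthetic cohort generator

The generator defines the study conditions under which everything above is
tested; its defaults are fixed, not tuned.

* **Cohort sizes**: 82 intervention users with logs over days 1–155, 84
  TAU users with outcomes only — the reference trial's analyzable sample.
* **Archetypes**: three latent engagement archetypes with prevalences
  0.60/0.23/0.17, assigned by deterministic largest-remainder quota (so the
  default cohort always splits 49/19/14, giving stable test fixtures).
  Each archetype specifies, per week, a probability distribution over the
  four levels on each dimension; the shapes emulate the qualitative
  trajectory patterns of the reference cohort — *low use* (brief initial
  exploration, then near-silence), *maintained social* (social use
  persists at the like/react level while therapy fades to passive), and
  *maintained therapy and social* (variable but sustained active use of
  both, tapering in the final weeks). Anchor distributions are linearly
  interpolated across weeks.
* **Emission**: every post-induction user-day draws one (therapy, social)
  level pair from its week's distribution and emits raw counts *minimally
  sufficient* for that pair (e.g. exactly one step or one action for
  engaged therapy; a uniformly chosen pattern of two steps / two actions /
  one of each, plus level-preserving extras, for highly engaged), with
  optional passive visits that cannot change the category. Re-categorizing
  the emitted log therefore reproduces the drawn levels exactly for 100% of
  user-days — the generator's core contract, asserted by tests.
* **Randomness**: a single global seed fans out to one `SeedSequence`
  substream per user, so an individual user's data is reproducible
  regardless of cohort composition or ordering.
* **Outcomes**: `value(u,t) = baseline_mean + b_u + shift_g·1[t=6mo] +
  covariate terms + ε`, with `b_u ~ N(0, τ²)`, `ε ~ N(0, σ²)`. Default
  effect specs cover the full 11-outcome battery with planted shifts
  mirroring the reference model-implied changes (e.g. PSP +11.0 for the
  maintained-therapy-and-social profile, roughly flat elsewhere) and
  variance components giving an intraclass correlation near 0.5.
  Covariates are generator conventions, as the trial reports only the age
  range: sex ~ Bernoulli(½), age ~ discrete uniform 16–27 years,
  duration of untreated psychosis ~ log-normal with median 60 days; their
  coefficients act on centered covariates so `baseline_mean` keeps its
  interpretation. An optional missingness rate drops 6-month rows.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: event timestamps and session structure,
moderator and peer-moderator behaviour, message content, within-week
autocorrelation of activity (days are conditionally independent given the
week's distribution), baseline clinical differences between engagement
profiles (the reference cohort's maintained-therapy-and-social users had
higher baseline negative symptoms; the generator plants a common baseline
mean), non-normal outcome distributions, and informative dropout.

## Numerical and testing notes

* Validity indices and the Rand index are verified against independent
  brute-force implementations to 1e-10 on small instances, and against
  scikit-learn where it implements the same definition (CH, DB, Rand,
  adjusted Rand).
* Mixed-model calibration uses 500 null replicates (type-I error band
  0.03–0.07 at α = .05) and 200 effect replicates (bias < 5%, coverage
  90–98%) at the reference profile sizes; heavier replication would
  sharpen the bands but adds nothing qualitative. Selection-recovery
  experiments use 20 cohort seeds with 100 clustering restarts and
  lightened stability resampling (stability only breaks ties).
* Degenerate inputs: zero-residual data fit cleanly (the REML boundary is
  handled and contrasts remain exact); `K = n` yields zero inertia;
  coincident centroids and empty clusters raise explicit errors rather
  than returning NaN.
* The pipeline is deterministic for a fixed seed; every artifact records
  the seed and a hash of the analysis-relevant configuration.
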