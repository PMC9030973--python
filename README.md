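# engagement-profiles

Engagement profiling for multicomponent digital mental-health interventions:
from raw per-user per-day usage logs to data-driven *user profiles* and their
predictive value for clinical outcomes.

Platforms that combine interactive therapy modules with a moderated social
network give users freedom in how they engage, so simple metrics (log-ins,
module counts) hide the patterns that matter. This package implements the
full analysis chain used to characterize such platforms in first-episode
psychosis research:

1. **Hierarchical 2D daily activity levels.** Thirteen raw metrics per
   user-day (steps started, actions done, posts, comments, likes, reactions,
   page visits, …) are reduced to an ordinal level 1–4 on each of two
   dimensions:

   | level | therapy dimension | social dimension |
   |---|---|---|
   | 1 | inactive | inactive |
   | 2 | passive (visits only) | passive (visits only) |
   | 3 | engaged — started 1 step or did 1 action | moderate — liked/reacted to ≥ 1 item |
   | 4 | highly engaged — > 1 step, > 1 action, or ≥ 1 of each | active — posted or commented |

2. **Weekly joint trajectories.** Daily levels over days 2–155 of each
   user's trial involvement (day 1 is platform induction; 154 days = 22
   weeks) are aggregated into 22 weekly scores per dimension — the
   *maximum* daily level within each 7-day block — giving each user a
   2 × 22 trajectory matrix.

3. **K-means clustering for joint trajectories.** Users are partitioned by
   Euclidean distance on the flattened 44-vector, with 100 restarts cycling
   through three initialization schemes. Solutions for K = 2…4 are compared
   with Calinski–Harabasz (higher better), Ray–Turi and Davies–Bouldin
   (lower better) indices; solutions with any cluster under 15 members are
   excluded; stability is quantified by the Rand index over 100 subsample
   resamples.

4. **Outcome models.** Profiles are characterized at baseline (one-way
   ANOVA / chi-square, Tukey HSD post hoc) and their predictive value for
   change in clinical scales (PSP, FESFS subscales, PANSS, CDSS, DASS
   anxiety) is estimated with linear mixed models
   `value ~ group * time + sex + age + log(DUP) + (1 | user)` fitted by
   REML, with Satterthwaite-type denominator degrees of freedom, post-hoc
   time-within-group and group-at-time contrasts, and optional comparison of
   each profile against a treatment-as-usual (TAU) arm.

Because trial usage logs of this kind are not publicly deposited, the
package ships a synthetic-cohort generator with three latent engagement
archetypes (*low use*, *maintained social*, *maintained therapy and
social*, prevalences 0.60/0.23/0.17) whose emitted raw metrics are
guaranteed to re-categorize to the drawn activity levels, plus a
longitudinal outcome simulator with planted group × time effects — so
cluster recovery and effect estimation are testable end to end.

## Worked example

Run the full pipeline on a simulated 82-user intervention cohort (plus 84
TAU users) and inspect the selection report:

```sh
engagement-profiles run-all --seed 1 --out demo
```

```
  k         CH   Ray-Turi         DB  meanRand  minsize status
  2     89.268     0.2155     0.9236    1.0000       33 votes=3  <- selected
  3     67.571     0.3497     0.9424    1.0000       14 smallest cluster has 14 members (< 15)
  4     48.495     2.4887     2.2063    0.8915       14 smallest cluster has 14 members (< 15)
```

All three validity indices favour K = 2 and the 3- and 4-cluster solutions
are excluded because the smallest planted profile (17% of 82 users = 14)
sits just under the 15-member floor — the same tension reported for the
real cohort, where the selected 3-cluster solution contained a 14-member
profile and the 2-cluster solution scored best on every nonparametric
index. The tool never overrides silently; to examine the 3-profile
solution, pin the candidate range:

```sh
engagement-profiles cluster --input demo/trajectories.csv \
    --k-min 3 --k-max 3 --min-cluster-size 14 --seed 1 --out demo/solution_k3.json
engagement-profiles analyze --outcomes demo/outcomes.csv \
    --labels demo/solution_k3.json --compare profiles --out demo/results_k3.json
```

The recovered profiles have sizes 49/14/19 (subsample mean Rand 1.00
against the full-data partition), and the outcome models find the planted
pattern: the maintained-therapy-and-social profile improves on social
functioning while the others stay flat —

```
PSP:            group x time F = 15.19 (2, 79), p < .001
PANSS negative: group x time F =  9.20 (2, 79), p < .001
PANSS total:    group x time F =  7.52 (2, 79), p = .001
CDSS:           group x time F =  0.37 (2, 79), p = .69

PSP model-implied means, profile_1 (n=14): 67.7 -> 81.7
  time-within-group contrast +14.0, F(1, 79), p < .001
  (other profiles: +1.3, p = .29; -2.1, p = .30)
```

(The generator plants a +11-point PSP shift for that profile; seed-1
sampling noise puts the estimate at +14.0 with a standard error of ~2.8.)
Every artifact (CSV, JSON, Markdown report, trajectory and mean-trend
plots) carries the seed and a configuration hash.

The same stages are available programmatically
(`generate_cohort`, `build_trajectory_matrix`, `select_solution`,
`analyze_outcomes`) and via per-stage subcommands
(`simulate`, `trajectories`, `cluster`, `analyze`), configurable through a
YAML file (`run-all --config config.yaml`).

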