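"""Synthetic cohort generator with known latent engagement structure.

Real engagement logs from the trial platform are not publicly deposited, so
this module simulates the three tables the analysis pipeline consumes:

* a usage log (one row per intervention user per day, 13 raw metrics),
* a longitudinal outcomes table (baseline and 6 months, intervention + TAU),
* a truth table mapping each intervention user to their latent archetype.

Users belong to latent engagement *archetypes*, each described by per-week
probability distributions over the four ordinal activity levels on the
therapy and social dimensions.  Every post-induction user-day draws a target
(therapy, social) level pair from the archetype's distribution for the week
containing that day, and raw counts consistent with that pair under the
hierarchical categorization rules are emitted — so re-categorizing the log
recovers the drawn levels exactly, which is the generator's core testable
contract.

Outcomes follow a linear mixed model: per-user random intercept, fixed
group shift at follow-up (the planted group x time interaction), covariate
contributions (sex, age, log duration of untreated psychosis) and Gaussian
residual noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity_engagement import (
    DEFAULT_N_WEEKS,
    DEFAULT_START_DAY,
    INDUCTION_DAY,
    LOG_COLUMNS,
    USAGE_COLS,
)

N_LEVELS = 4
#: Trial defaults: 82 intervention users observed over days 1-155, 84 TAU.
DEFAULT_N_USERS = 82
DEFAULT_N_TAU = 84
DEFAULT_N_DAYS = 155
AGE_RANGE = (16, 27)  # years at randomization, inclusive
TIMEPOINTS = (0, 6)  # months


# ---------------------------------------------------------------------------
# Archetype specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeSpec:
    """A latent engagement archetype.

    ``therapy_level_probs`` and ``social_level_probs`` are (n_weeks, 4)
    arrays; row w gives the distribution of a single day's activity level
    during week w+1.  ``prevalence`` is the archetype's cohort fraction.
    """

    name: str
    therapy_level_probs: np.ndarray
    social_level_probs: np.ndarray
    prevalence: float

    def __post_init__(self):
        for attr in ("therapy_level_probs", "social_level_probs"):
            probs = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, probs)
            if probs.shape != (DEFAULT_N_WEEKS, N_LEVELS):
                raise ValueError(
                    f"{self.name}.{attr}: expected shape {(DEFAULT_N_WEEKS, N_LEVELS)}, "
                    f"got {probs.shape}"
                )
            if (probs < 0).any():
                raise ValueError(f"{self.name}.{attr}: negative probabilities")
            if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{self.name}.{attr}: rows must sum to 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence outside [0, 1]")


def _interp_probs(anchors: dict[int, tuple[float, float, float, float]]) -> np.ndarray:
    """Linear interpolation between per-week anchor distributions, renormalized."""
    weeks = np.arange(1, DEFAULT_N_WEEKS + 1)
    xs = sorted(anchors)
    table = np.vstack([anchors[w] for w in xs])
    out = np.empty((DEFAULT_N_WEEKS, N_LEVELS))
    for lvl in range(N_LEVELS):
        out[:, lvl] = np.interp(weeks, xs, table[:, lvl])
    return out / out.sum(axis=1, keepdims=True)


def default_archetypes() -> list[ArchetypeSpec]:
    """The three engagement archetypes the pipeline is designed to recover.

    Shapes emulate the qualitative trajectory patterns observed on the real
    platform: *low use* (brief initial exploration then near-silence),
    *maintained social* (social-network use persists at the moderate,
    like/react level while therapy use fades to passive visits) and
    *maintained therapy and social* (variable but sustained active use of
    both components, tapering only in the final weeks).  Prevalences follow
    the observed 60/23/17 split.
    """
    low = ArchetypeSpec(
        name="low_use",
        therapy_level_probs=_interp_probs({
            1: (0.15, 0.15, 0.35, 0.35),
            3: (0.55, 0.25, 0.15, 0.05),
            6: (0.93, 0.05, 0.015, 0.005),
            22: (0.97, 0.02, 0.007, 0.003),
        }),
        social_level_probs=_interp_probs({
            1: (0.12, 0.18, 0.35, 0.35),
            3: (0.55, 0.25, 0.15, 0.05),
            6: (0.93, 0.05, 0.015, 0.005),
            22: (0.97, 0.02, 0.007, 0.003),
        }),
        prevalence=0.60,
    )
    social = ArchetypeSpec(
        name="maintained_social",
        therapy_level_probs=_interp_probs({
            1: (0.10, 0.20, 0.35, 0.35),
            4: (0.35, 0.35, 0.25, 0.05),
            8: (0.70, 0.25, 0.045, 0.005),
            22: (0.85, 0.13, 0.015, 0.005),
        }),
        social_level_probs=_interp_probs({
            1: (0.05, 0.10, 0.45, 0.40),
            6: (0.15, 0.20, 0.55, 0.10),
            18: (0.25, 0.25, 0.45, 0.05),
            22: (0.50, 0.25, 0.22, 0.03),
        }),
        prevalence=0.23,
    )
    both = ArchetypeSpec(
        name="maintained_therapy_social",
        therapy_level_probs=_interp_probs({
            1: (0.10, 0.15, 0.40, 0.35),
            10: (0.20, 0.20, 0.40, 0.20),
            18: (0.25, 0.20, 0.40, 0.15),
            22: (0.60, 0.20, 0.15, 0.05),
        }),
        social_level_probs=_interp_probs({
            1: (0.05, 0.10, 0.40, 0.45),
            10: (0.15, 0.15, 0.45, 0.25),
            18: (0.20, 0.15, 0.45, 0.20),
            22: (0.55, 0.20, 0.18, 0.07),
        }),
        prevalence=0.17,
    )
    return [low, social, both]


def allocate_archetypes(archetypes: list[ArchetypeSpec], n_users: int) -> list[int]:
    """Deterministic largest-remainder quota allocation of users to archetypes.

    Returns per-archetype counts summing to ``n_users``.  Quotas are
    n_users * prevalence; floors are topped up in order of descending
    fractional remainder (ties broken by archetype order).
    """
    if n_users <= 0:
        raise ValueError("n_users must be positive")
    prevalences = np.array([a.prevalence for a in archetypes], dtype=float)
    if not math.isclose(prevalences.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"prevalences sum to {prevalences.sum()}, not 1")
    quotas = prevalences * n_users
    counts = np.floor(quotas).astype(int)
    remainder = n_users - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# Raw-count emission
# ---------------------------------------------------------------------------

def _emit_days(
    t_levels: np.ndarray, s_levels: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Emit raw metrics for a run of days whose categorizations are given.

    Counts are sampled minimally sufficient for each target level, with
    optional extras that cannot change the category (extra steps/actions at
    level 4, extra likes at level 3, passive visits at any level >= 2).
    Vectorized over days; one call per user keeps per-user substreams intact.
    """
    n = len(t_levels)
    cols = {c: np.zeros(n, dtype=int) for c in USAGE_COLS}

    t2, t3, t4 = (t_levels == lv for lv in (2, 3, 4))
    which = rng.integers(3, size=n)  # therapy page, suggested content, or both
    cols["visited_therapy"][t2 & (which != 1)] = 1
    cols["visited_suggested_content"][t2 & (which != 0)] = 1
    coin = rng.integers(2, size=n)  # one step xor one action
    cols["steps_started"][t3 & (coin == 1)] = 1
    cols["actions_done"][t3 & (coin == 0)] = 1
    base = rng.integers(3, size=n)  # (2 steps | 2 actions | 1 of each) + extras
    cols["steps_started"][t4] = (
        np.array((2, 0, 1))[base] + rng.poisson(0.7, size=n)
    )[t4]
    cols["actions_done"][t4] = (
        np.array((0, 2, 1))[base] + rng.poisson(0.7, size=n)
    )[t4]
    active_t = t3 | t4  # active users may also browse
    cols["visited_therapy"][active_t & (rng.random(n) < 0.6)] = 1
    cols["visited_suggested_content"][active_t & (rng.random(n) < 0.2)] = 1

    s2 = s_levels == 2
    s34 = s_levels >= 3
    s4 = s_levels == 4
    passive_cols = (
        "visited_messages", "visited_notifications", "visited_newsfeed",
        "visited_talk_it_out",
    )
    flags = rng.random((n, 4)) < (0.3, 0.3, 0.7, 0.2)
    flags[~flags.any(axis=1), 2] = True  # guarantee at least one visit
    for j, col in enumerate(passive_cols):
        cols[col][s2 & flags[:, j]] = 1
    likes = rng.poisson(1.0, size=n)
    reactions = rng.poisson(0.5, size=n)
    likes[(s_levels == 3) & (likes + reactions == 0)] = 1  # moderate needs >= 1
    cols["likes_made"][s34] = likes[s34]
    cols["reactions_made"][s34] = reactions[s34]
    contrib = rng.integers(3, size=n)  # post, comment, or forum post + extras
    cols["newsfeed_posts"][s4] = (
        (contrib == 0).astype(int) + rng.poisson(0.4, size=n)
    )[s4]
    cols["newsfeed_comments"][s4] = (
        (contrib == 1).astype(int) + rng.poisson(0.6, size=n)
    )[s4]
    cols["talk_it_out_posts"][s4] = (
        (contrib == 2).astype(int) + rng.poisson(0.2, size=n)
    )[s4]
    cols["visited_newsfeed"][s34 & (rng.random(n) < 0.8)] = 1
    cols["visited_notifications"][s34 & (rng.random(n) < 0.4)] = 1
    cols["visited_messages"][s34 & (rng.random(n) < 0.3)] = 1
    p_tio = np.where(cols["talk_it_out_posts"] > 0, 0.6, 0.15)
    cols["visited_talk_it_out"][s34 & (rng.random(n) < p_tio)] = 1
    return cols


def _induction_row(rng: np.random.Generator) -> dict[str, int]:
    """Day-1 induction: guided tour, logged as passive visits on both sides."""
    row = dict.fromkeys(USAGE_COLS, 0)
    row["visited_therapy"] = 1
    row["visited_newsfeed"] = 1
    row["visited_notifications"] = int(rng.random() < 0.5)
    return row


def generate_usage_logs(
    archetypes: list[ArchetypeSpec] | None = None,
    n_users: int = DEFAULT_N_USERS,
    n_days: int = DEFAULT_N_DAYS,
    seed: int = 0,
    start_day: int = DEFAULT_START_DAY,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the usage log for an intervention cohort.

    Returns ``(log, truth, levels)``:

    * ``log`` — one row per user-day with the 13 raw metrics,
    * ``truth`` — user_id -> archetype name,
    * ``levels`` — the drawn (therapy, social) level pair per post-induction
      user-day, for round-trip verification against re-categorization.

    A single global seed fans out to one independent substream per user, so
    an individual user's data is reproducible regardless of cohort order.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if n_users <= 0 or n_days <= 0:
        raise ValueError("n_users and n_days must be positive")
    counts = allocate_archetypes(archetypes, n_users)

    membership: list[ArchetypeSpec] = []
    for arch, cnt in zip(archetypes, counts):
        membership.extend([arch] * cnt)

    streams = np.random.SeedSequence(seed).spawn(n_users)
    days = np.arange(start_day, n_days + 1)
    weeks = np.minimum((days - start_day) // 7, DEFAULT_N_WEEKS - 1)
    frames: list[pd.DataFrame] = []
    level_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for i, (arch, ss) in enumerate(zip(membership, streams)):
        rng = np.random.default_rng(ss)
        user = f"U{i + 1:03d}"
        truth_rows.append({"user_id": user, "archetype": arch.name})
        # inverse-CDF draw of one level pair per post-induction day
        u = rng.random((len(days), 2))
        t_levels = (
            u[:, 0:1] > arch.therapy_level_probs.cumsum(axis=1)[weeks]
        ).sum(axis=1) + 1
        s_levels = (
            u[:, 1:2] > arch.social_level_probs.cumsum(axis=1)[weeks]
        ).sum(axis=1) + 1
        cols = _emit_days(t_levels, s_levels, rng)
        induction = {"user_id": user, "day_index": INDUCTION_DAY,
                     **_induction_row(rng)}
        frames.append(
            pd.concat(
                [
                    pd.DataFrame([induction]),
                    pd.DataFrame({"user_id": user, "day_index": days, **cols}),
                ],
                ignore_index=True,
            )
        )
        level_frames.append(
            pd.DataFrame(
                {
                    "user_id": user,
                    "day_index": days,
                    "therapy_level": t_levels,
                    "social_level": s_levels,
                }
            )
        )
    log = pd.concat(frames, ignore_index=True)[LOG_COLUMNS]
    truth = pd.DataFrame(truth_rows)
    levels = pd.concat(level_frames, ignore_index=True)
    return log, truth, levels


# ---------------------------------------------------------------------------
# Longitudinal outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeEffectSpec:
    """Planted data-generating parameters for one clinical outcome.

    ``group_time_shift`` maps each group label (archetype names plus "TAU")
    to its mean change from baseline to 6 months; the differences between
    those shifts are the planted group x time interactions.  ``baseline_sd``
    documents the target marginal between-user spread at baseline; the
    generative spread is carried by ``random_intercept_sd`` (between users)
    and ``residual_sd`` (within user-timepoint).  Covariate coefficients
    apply to centered covariates: sex - 1/2, age - 21 years,
    log(DUP days) - log(60).
    """

    outcome_name: str
    baseline_mean: float
    baseline_sd: float
    group_time_shift: dict[str, float]
    residual_sd: float
    random_intercept_sd: float
    sex_beta: float = 0.0
    age_beta: float = 0.0
    dup_beta: float = 0.0

    def __post_init__(self):
        for attr in ("baseline_sd", "residual_sd", "random_intercept_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.outcome_name}: {attr} must be nonnegative")


def default_outcome_effects(
    groups: tuple[str, ...] = (
        "low_use",
        "maintained_social",
        "maintained_therapy_social",
        "TAU",
    ),
) -> list[OutcomeEffectSpec]:
    """Default effect specs covering the full outcome battery.

    Planted shifts mirror the model-implied 6-month-minus-baseline changes
    reported for the trial (e.g. PSP +11.0 for the maintained therapy and
    social profile, roughly flat elsewhere); variance components are chosen
    to give a within/between split typical of these instruments.
    """
    # (baseline_mean, baseline_sd, shifts per group, residual_sd, ri_sd)
    low, soc, both, tau = groups
    table = {
        "PSP": (66.5, 12.0, {low: 1.6, soc: -3.1, both: 11.0, tau: 1.7}, 7.0, 7.0),
        "FESFS_living_skills": (13.6, 2.1, {low: -0.1, soc: 0.0, both: -0.1, tau: 0.0}, 1.3, 1.6),
        "FESFS_interacting": (12.7, 2.2, {low: 0.3, soc: -0.4, both: 0.4, tau: -0.2}, 1.4, 1.7),
        "FESFS_friends_activities": (18.5, 3.0, {low: 0.6, soc: 0.2, both: 0.5, tau: -0.2}, 1.9, 2.3),
        "FESFS_intimacy": (15.0, 2.8, {low: -0.1, soc: -0.5, both: -1.0, tau: -0.1}, 1.8, 2.2),
        "PANSS_total": (45.0, 11.5, {low: -0.2, soc: 3.1, both: -7.2, tau: 1.5}, 7.0, 9.0),
        "PANSS_positive": (10.4, 2.9, {low: -0.2, soc: 0.9, both: -0.4, tau: 0.3}, 1.8, 2.2),
        "PANSS_negative": (11.3, 3.6, {low: -0.7, soc: -0.7, both: -4.3, tau: -0.4}, 2.2, 2.8),
        "PANSS_general": (23.7, 5.8, {low: 0.7, soc: 2.9, both: -2.4, tau: 1.6}, 3.6, 4.5),
        "CDSS": (3.6, 3.3, {low: 0.5, soc: 0.5, both: -0.6, tau: 0.7}, 2.1, 2.6),
        "DASS_anxiety": (11.5, 6.7, {low: -0.1, soc: 3.8, both: -0.7, tau: -3.4}, 4.2, 5.2),
    }
    return [
        OutcomeEffectSpec(
            outcome_name=name,
            baseline_mean=mean,
            baseline_sd=sd,
            group_time_shift=dict(shifts),
            residual_sd=res,
            random_intercept_sd=ri,
            sex_beta=-0.1 * sd,
            age_beta=0.02 * sd,
            dup_beta=-0.05 * sd,
        )
        for name, (mean, sd, shifts, res, ri) in table.items()
    ]


def generate_covariates(user_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-user covariates: sex (0/1), age 16-27 years, DUP days.

    Distributions are generator conventions (the trial reports only the age
    range and that DUP was an a-priori covariate): sex ~ Bernoulli(1/2),
    age ~ discrete uniform on 16..27, DUP ~ log-normal with median 60 days.
    """
    return pd.DataFrame(
        {
            "user_id": user_ids,
            "sex": rng.integers(0, 2, size=len(user_ids)),
            "age": rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=len(user_ids)),
            "dup_days": np.round(
                np.exp(rng.normal(np.log(60.0), 0.9, size=len(user_ids))), 1
            ),
        }
    )


def generate_outcomes(
    truth: pd.DataFrame,
    effects: list[OutcomeEffectSpec] | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate the longitudinal outcomes table for labeled users.

    ``truth`` must have columns user_id and group (or archetype); a group
    label "TAU" marks control-arm users.  For user u at timepoint t:

        value = baseline_mean + b_u + shift_{group(u)} * 1[t = 6]
                + covariate contributions + eps

    with b_u ~ N(0, random_intercept_sd^2), eps ~ N(0, residual_sd^2).
    ``missing_rate`` drops each 6-month row independently with that
    probability (baseline rows are always kept).
    """
    if effects is None:
        effects = default_outcome_effects()
    frame = truth.rename(columns={"archetype": "group"})
    if not {"user_id", "group"} <= set(frame.columns):
        raise ValueError("truth must have columns user_id and group/archetype")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    groups = set(frame["group"])
    for eff in effects:
        unknown = groups - set(eff.group_time_shift)
        if unknown:
            raise ValueError(
                f"{eff.outcome_name}: no planted shift for groups {sorted(unknown)}"
            )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0C0]))
    users = frame["user_id"].tolist()
    covariates = generate_covariates(users, rng)
    merged = frame.merge(covariates, on="user_id")

    sex_c = merged["sex"].to_numpy() - 0.5
    age_c = merged["age"].to_numpy() - 21.0
    dup_c = np.log(merged["dup_days"].to_numpy()) - np.log(60.0)
    n = len(merged)

    rows = []
    for eff in effects:
        b_u = rng.normal(0.0, eff.random_intercept_sd, size=n)
        shift = merged["group"].map(eff.group_time_shift).to_numpy(float)
        cov = eff.sex_beta * sex_c + eff.age_beta * age_c + eff.dup_beta * dup_c
        for t in TIMEPOINTS:
            eps = rng.normal(0.0, eff.residual_sd, size=n)
            value = eff.baseline_mean + b_u + cov + (shift if t else 0.0) + eps
            keep = (
                np.ones(n, bool)
                if (t == 0 or missing_rate == 0.0)
                else rng.random(n) >= missing_rate
            )
            for i in np.flatnonzero(keep):
                rows.append(
                    {
                        "user_id": merged["user_id"].iat[i],
                        "arm": "TAU" if merged["group"].iat[i] == "TAU" else "intervention",
                        "group": merged["group"].iat[i],
                        "timepoint": t,
                        "outcome_name": eff.outcome_name,
                        "value": value[i],
                        "sex": merged["sex"].iat[i],
                        "age": merged["age"].iat[i],
                        "dup_days": merged["dup_days"].iat[i],
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated trial produces."""

    usage_log: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    levels: pd.DataFrame
    effects: list[OutcomeEffectSpec] = field(default_factory=list)


def generate_cohort(
    archetypes: list[ArchetypeSpec] | None = None,
    effects: list[OutcomeEffectSpec] | None = None,
    n_users: int = DEFAULT_N_USERS,
    n_tau: int = DEFAULT_N_TAU,
    n_days: int = DEFAULT_N_DAYS,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> SyntheticCohort:
    """Simulate a full trial: usage logs plus outcomes for both arms."""
    if archetypes is None:
        archetypes = default_archetypes()
    if effects is None:
        effects = default_outcome_effects(
            tuple(a.name for a in archetypes) + ("TAU",)
        )
    log, truth, levels = generate_usage_logs(
        archetypes, n_users=n_users, n_days=n_days, seed=seed
    )
    tau = pd.DataFrame(
        {"user_id": [f"T{i + 1:03d}" for i in range(n_tau)], "archetype": "TAU"}
    )
    labels = pd.concat([truth, tau], ignore_index=True)
    outcomes = generate_outcomes(
        labels, effects=effects, seed=seed, missing_rate=missing_rate
    )
    return SyntheticCohort(
        usage_log=log, outcomes=outcomes, truth=truth, levels=levels, effects=effects
    )
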