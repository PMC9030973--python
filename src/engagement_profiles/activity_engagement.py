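"""Hierarchical 2D daily activity categorization and weekly trajectory building.

Raw per-user per-day usage metrics from a moderated online social therapy
platform are reduced to an ordinal (therapy, social) activity-level pair per
day, then aggregated into 22 weekly scores per dimension (the maximum daily
level within each 7-day block).  The resulting per-user 2x22 matrices are the
input features for joint-trajectory clustering.

Activity levels on both dimensions:

    1  inactive        no activity at all on that component
    2  passive         visited pages only, no active engagement
    3  engaged (therapy) / moderate (social)
                       started 1 step or completed 1 action /
                       liked or reacted to >=1 item without contributing
    4  highly engaged (therapy) / active (social)
                       >1 step, >1 action, or >=1 of each /
                       contributed a post or comment

Day 1 of each user's trial involvement is an induction session and never
contributes; weeks are fixed 7-day blocks anchored at day 2 of each user's
own timeline (days 2-155 = 154 days = 22 weeks by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

# Raw usage-log schema: therapy-related then social-networking-related metrics.
THERAPY_COUNT_COLS = ["steps_started", "actions_done"]
THERAPY_VISIT_COLS = ["visited_suggested_content", "visited_therapy"]
SOCIAL_CONTRIB_COLS = ["newsfeed_posts", "newsfeed_comments", "talk_it_out_posts"]
SOCIAL_REACT_COLS = ["likes_made", "reactions_made"]
SOCIAL_VISIT_COLS = [
    "visited_messages",
    "visited_notifications",
    "visited_newsfeed",
    "visited_talk_it_out",
]
COUNT_COLS = THERAPY_COUNT_COLS + SOCIAL_CONTRIB_COLS + SOCIAL_REACT_COLS
VISIT_COLS = THERAPY_VISIT_COLS + SOCIAL_VISIT_COLS
USAGE_COLS = (
    THERAPY_COUNT_COLS
    + THERAPY_VISIT_COLS
    + SOCIAL_CONTRIB_COLS
    + SOCIAL_REACT_COLS
    + SOCIAL_VISIT_COLS
)
LOG_COLUMNS = ["user_id", "day_index"] + USAGE_COLS

#: Default analysis window: days 2-155 inclusive, 22 seven-day weeks.
DEFAULT_START_DAY = 2
DEFAULT_N_WEEKS = 22
INDUCTION_DAY = 1


class DailyActivityPair(NamedTuple):
    """Ordinal (therapy, social) activity level for one user-day."""

    therapy_level: int
    social_level: int


@dataclass(frozen=True)
class WeeklyTrajectory:
    """Weekly maximum activity levels for one user, both dimensions."""

    user_id: str
    therapy_scores: np.ndarray  # (n_weeks,) ints in 1..4
    social_scores: np.ndarray  # (n_weeks,) ints in 1..4

    def as_matrix(self) -> np.ndarray:
        """Return the 2 x n_weeks array (therapy row first)."""
        return np.vstack([self.therapy_scores, self.social_scores])


@dataclass
class TrajectoryMatrix:
    """Stacked per-user weekly trajectories: the clustering input.

    ``values`` has shape (n_users, 2, n_weeks); axis 1 is (therapy, social).
    Users with no post-induction log rows appear as all-ones trajectories and
    are listed in ``silent_users``.
    """

    users: list[str]
    values: np.ndarray
    silent_users: list[str]

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_weeks(self) -> int:
        return self.values.shape[2]

    def flattened(self) -> np.ndarray:
        """(n_users, 2*n_weeks) view used for distance computations."""
        return self.values.reshape(self.n_users, -1)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: user_id, t_w1..t_wW, s_w1..s_wW."""
        w = self.n_weeks
        cols = [f"t_w{i}" for i in range(1, w + 1)] + [f"s_w{i}" for i in range(1, w + 1)]
        return pd.DataFrame(self.flattened(), columns=cols).assign(user_id=self.users)[
            ["user_id"] + cols
        ]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrajectoryMatrix":
        t_cols = sorted(
            (c for c in frame.columns if c.startswith("t_w")), key=lambda c: int(c[3:])
        )
        s_cols = sorted(
            (c for c in frame.columns if c.startswith("s_w")), key=lambda c: int(c[3:])
        )
        if len(t_cols) != len(s_cols) or not t_cols:
            raise ValueError("frame lacks matching t_w*/s_w* trajectory columns")
        values = np.stack(
            [frame[t_cols].to_numpy(float), frame[s_cols].to_numpy(float)], axis=1
        )
        return cls(users=list(frame["user_id"].astype(str)), values=values, silent_users=[])

    @classmethod
    def read_csv(cls, path) -> "TrajectoryMatrix":
        # tolerate the provenance comment header the pipeline prepends
        return cls.from_frame(pd.read_csv(path, comment="#"))


def _validate_row(row: Mapping) -> None:
    for col in COUNT_COLS:
        if row[col] < 0:
            raise ValueError(f"negative count in {col!r}: {row[col]}")
    for col in VISIT_COLS:
        if row[col] not in (0, 1):
            raise ValueError(f"visit flag {col!r} must be 0/1, got {row[col]}")


def categorize_day(row: Mapping) -> DailyActivityPair:
    """Categorize one day of raw metrics into the hierarchical 2D levels.

    ``row`` is any mapping (dict, pandas Series) exposing the 13 usage
    columns.  The hierarchy is evaluated top-down so each dimension gets
    exactly one level; ties resolve to the highest applicable level.
    """
    _validate_row(row)
    steps, actions = row["steps_started"], row["actions_done"]
    if steps > 1 or actions > 1 or (steps >= 1 and actions >= 1):
        therapy = 4
    elif steps + actions == 1:
        therapy = 3
    elif any(row[c] for c in THERAPY_VISIT_COLS):
        therapy = 2
    else:
        therapy = 1

    contributions = sum(row[c] for c in SOCIAL_CONTRIB_COLS)
    likes_reactions = sum(row[c] for c in SOCIAL_REACT_COLS)
    if contributions >= 1:
        social = 4
    elif likes_reactions >= 1:
        social = 3
    elif any(row[c] for c in SOCIAL_VISIT_COLS):
        social = 2
    else:
        social = 1
    return DailyActivityPair(therapy, social)


def categorize_log(log: pd.DataFrame) -> pd.DataFrame:
    """Vectorized categorization of a whole usage-log table.

    Returns a frame with columns user_id, day_index, therapy_level,
    social_level.  Duplicate (user_id, day_index) rows are rejected.
    """
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"usage log missing columns: {missing}")
    if log.duplicated(subset=["user_id", "day_index"]).any():
        dups = log[log.duplicated(subset=["user_id", "day_index"], keep=False)]
        raise ValueError(
            "duplicate (user_id, day_index) rows: "
            + ", ".join(map(str, dups[["user_id", "day_index"]].head(5).to_numpy().tolist()))
        )
    counts = log[COUNT_COLS].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative counts in usage log")
    flags = log[VISIT_COLS].to_numpy()
    if ~np.isin(flags, (0, 1)).all():
        raise ValueError("visit flags must be 0/1")

    steps = log["steps_started"].to_numpy()
    actions = log["actions_done"].to_numpy()
    therapy_visit = log[THERAPY_VISIT_COLS].to_numpy().any(axis=1)
    therapy = np.ones(len(log), dtype=int)
    therapy[therapy_visit] = 2
    therapy[(steps + actions) == 1] = 3
    therapy[(steps > 1) | (actions > 1) | ((steps >= 1) & (actions >= 1))] = 4

    contributions = log[SOCIAL_CONTRIB_COLS].to_numpy().sum(axis=1)
    likes_reactions = log[SOCIAL_REACT_COLS].to_numpy().sum(axis=1)
    social_visit = log[SOCIAL_VISIT_COLS].to_numpy().any(axis=1)
    social = np.ones(len(log), dtype=int)
    social[social_visit] = 2
    social[likes_reactions >= 1] = 3
    social[contributions >= 1] = 4

    return pd.DataFrame(
        {
            "user_id": log["user_id"].to_numpy(),
            "day_index": log["day_index"].to_numpy(),
            "therapy_level": therapy,
            "social_level": social,
        }
    )


def weekly_scores(
    daily: Mapping[int, DailyActivityPair] | Iterable[tuple[int, DailyActivityPair]],
    user_id: str = "",
    start_day: int = DEFAULT_START_DAY,
    n_weeks: int = DEFAULT_N_WEEKS,
) -> WeeklyTrajectory:
    """Aggregate daily level pairs into weekly maximum scores.

    Week ``w`` (1-based) covers days ``start_day + 7*(w-1)`` through
    ``start_day + 7*w - 1``.  Days without a record count as level 1
    (no platform contact) and the induction day (day 1) never contributes.
    """
    if n_weeks <= 0:
        raise ValueError("n_weeks must be positive")
    items = daily.items() if isinstance(daily, Mapping) else daily
    therapy = np.ones(n_weeks, dtype=int)
    social = np.ones(n_weeks, dtype=int)
    for day, pair in items:
        if day < 1:
            raise ValueError(f"day_index must be >= 1, got {day}")
        if day == INDUCTION_DAY or day < start_day:
            continue
        week = (day - start_day) // 7
        if week >= n_weeks:
            continue
        therapy[week] = max(therapy[week], pair[0])
        social[week] = max(social[week], pair[1])
    return WeeklyTrajectory(user_id=user_id, therapy_scores=therapy, social_scores=social)


def build_trajectory_matrix(
    log: pd.DataFrame,
    start_day: int = DEFAULT_START_DAY,
    n_weeks: int = DEFAULT_N_WEEKS,
) -> TrajectoryMatrix:
    """Categorize a usage log and assemble the n_users x 2 x n_weeks matrix.

    Users are ordered by sorted id so the result is independent of input row
    order.  Users whose only rows fall on the induction day (or who have no
    rows inside the window) are retained as all-ones trajectories and
    reported via ``silent_users``.
    """
    levels = categorize_log(log)
    users = sorted(levels["user_id"].astype(str).unique())
    index = {u: i for i, u in enumerate(users)}

    values = np.ones((len(users), 2, n_weeks), dtype=int)
    day = levels["day_index"].to_numpy()
    keep = (day != INDUCTION_DAY) & (day >= start_day) & (
        day < start_day + 7 * n_weeks
    )
    active = levels.loc[keep]
    weeks = (active["day_index"].to_numpy() - start_day) // 7
    rows = active["user_id"].astype(str).map(index).to_numpy()
    for dim, col in enumerate(["therapy_level", "social_level"]):
        lv = active[col].to_numpy()
        np.maximum.at(values, (rows, np.full_like(rows, dim), weeks), lv)

    contributing = set(active["user_id"].astype(str).unique())
    silent = [u for u in users if u not in contributing]
    return TrajectoryMatrix(users=users, values=values, silent_users=silent)
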