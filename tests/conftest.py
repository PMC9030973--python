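import numpy as np
import pandas as pd
import pytest

from engagement_profiles.activity_engagement import LOG_COLUMNS, USAGE_COLS


def make_log_row(user_id: str, day_index: int, **metrics) -> dict:
    """A usage-log row with all 13 metrics zero unless overridden."""
    row = dict.fromkeys(USAGE_COLS, 0)
    unknown = set(metrics) - set(USAGE_COLS)
    if unknown:
        raise KeyError(unknown)
    row.update(metrics)
    return {"user_id": user_id, "day_index": day_index, **row}


@pytest.fixture
def toy_log() -> pd.DataFrame:
    """Two users with hand-categorizable activity.

    User A: day 1 heavy use (induction, must be ignored); day 2 passive
    therapy visit (2,1); day 3 one step (3,1); day 9 likes only (1,3);
    day 20 a newsfeed post plus two steps (4,4).
    User B: day 2 no activity (1,1); day 155 one action plus one
    reaction (3,3) — the final day of the final week.
    """
    rows = [
        make_log_row("A", 1, steps_started=5, newsfeed_posts=3),
        make_log_row("A", 2, visited_therapy=1),
        make_log_row("A", 3, steps_started=1),
        make_log_row("A", 9, likes_made=2, visited_newsfeed=1),
        make_log_row("A", 20, newsfeed_posts=1, steps_started=2),
        make_log_row("B", 2),
        make_log_row("B", 155, actions_done=1, reactions_made=1),
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


@pytest.fixture
def toy_expected() -> np.ndarray:
    """Hand-computed 2 x 2 x 22 trajectory matrix for ``toy_log``.

    Weeks are 7-day blocks from day 2: week 1 = days 2-8, week 2 = days
    9-15, week 3 = days 16-22, ..., week 22 = days 149-155.
    """
    expected = np.ones((2, 2, 22), dtype=int)
    # user A (sorted first)
    expected[0, 0, 0] = 3  # therapy week 1: max(2, 3)
    expected[0, 1, 1] = 3  # social week 2: likes day 9
    expected[0, 0, 2] = 4  # therapy week 3: two steps day 20
    expected[0, 1, 2] = 4  # social week 3: newsfeed post day 20
    # user B
    expected[1, 0, 21] = 3  # therapy week 22: one action day 155
    expected[1, 1, 21] = 3  # social week 22: one reaction day 155
    return expected


@pytest.fixture(scope="session")
def default_cohort():
    """One default 82-user usage-log simulation shared across tests."""
    from engagement_profiles import generate_usage_logs

    log, truth, levels = generate_usage_logs(seed=1)
    return log, truth, levels


def blobs(n_per: tuple[int, ...], centers: np.ndarray, noise: float,
          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Planted trajectory-shaped clusters: (n, 2, W) data + labels."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for c, (n, center) in enumerate(zip(n_per, centers)):
        X.append(center + rng.normal(0.0, noise, size=(n,) + center.shape))
        labels += [c] * n
    return np.concatenate(X), np.asarray(labels)
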