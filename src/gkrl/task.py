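"""Three-armed bandit task with forced sampling and a hidden free-choice horizon.

Each game presents three decks of cards paying integer points in [1, 100].
A game starts with six forced choices that control how often each deck is
observed — either (2, 2, 2) across decks (equal information) or a permutation
of (4, 2, 0) (unequal information) — followed by 1–6 free choices whose count
(the horizon) is not cued.  Per-deck payoffs are Gaussian around a generative
mean that is stable within a game; means are built from a base of 30 or 50
points shifted by 0, 4, 12 or 20 points so a single draw does not reveal the
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_DECKS = 3

__all__ = [
    "TaskConfig",
    "Game",
    "draw_payoff",
    "make_game",
    "make_session",
    "session_to_frame",
    "session_from_frame",
]


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the bandit task.

    Defaults reproduce the scanner task: 128 games, payoff SD 8 points,
    payoffs clipped to [1, 100], six forced trials, horizons 1–6 with 6 the
    most frequent, and a 50/50 split of equal vs unequal information games.
    """

    n_games: int = 128
    base_means: tuple[float, ...] = (30.0, 50.0)
    adjustments: tuple[float, ...] = (0.0, 4.0, 12.0, 20.0)
    payoff_sd: float = 8.0
    payoff_bounds: tuple[int, int] = (1, 100)
    n_forced: int = 6
    horizon_range: tuple[int, int] = (1, 6)
    horizon_decay: float = 0.5
    p_equal_means: float = 0.5
    p_highhighlow_given_diff: float = 0.25
    p_unequal_info: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_equal_means", "p_highhighlow_given_diff", "p_unequal_info"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.payoff_bounds[0] >= self.payoff_bounds[1]:
            raise ValueError("payoff_bounds must be an increasing interval")
        if self.payoff_sd <= 0:
            raise ValueError("payoff_sd must be positive")
        if self.n_games < 0:
            raise ValueError("n_games must be nonnegative")
        if self.n_forced % N_DECKS != 0:
            raise ValueError(
                "n_forced must be divisible by the number of decks so the "
                "equal-information condition is well defined"
            )
        if not (0.0 < self.horizon_decay <= 1.0):
            raise ValueError("horizon_decay must lie in (0, 1]")
        lo, hi = self.horizon_range
        if not (1 <= lo <= hi):
            raise ValueError("horizon_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class Game:
    """One game: per-deck generative means, forced schedule and horizon."""

    game_id: int
    gen_means: tuple[float, float, float]
    info_condition: str  # "equal" | "unequal"
    forced_schedule: tuple[int, ...]
    horizon: int

    def forced_counts(self) -> np.ndarray:
        """Times each deck is sampled during the forced phase."""
        return np.bincount(np.asarray(self.forced_schedule), minlength=N_DECKS)


def draw_payoff(
    mean: float,
    sd: float,
    bounds: tuple[int, int],
    rng: np.random.Generator,
) -> int:
    """Draw one payoff: Gaussian, rounded to the nearest integer, clipped.

    Parameters
    ----------
    mean, sd
        Generative mean and standard deviation, in points.
    bounds
        Inclusive integer interval payoffs are clipped into.
    rng
        numpy random generator.
    """
    if not (np.isfinite(mean) and np.isfinite(sd)):
        raise ValueError("mean and sd must be finite")
    if sd <= 0:
        raise ValueError("sd must be positive")
    raw = rng.normal(mean, sd)
    return int(np.clip(np.rint(raw), bounds[0], bounds[1]))


def _sample_horizon(config: TaskConfig, rng: np.random.Generator) -> int:
    lo, hi = config.horizon_range
    horizons = np.arange(lo, hi + 1)
    # geometric shape: weight decay^(hi - h), mode at the longest horizon
    weights = config.horizon_decay ** (hi - horizons).astype(float)
    return int(rng.choice(horizons, p=weights / weights.sum()))


def make_game(config: TaskConfig, game_id: int, rng: np.random.Generator) -> Game:
    """Generate one game.

    With probability ``p_equal_means`` all three decks share a generative
    mean (base ± adjustment).  Otherwise two decks share one mean and the
    third differs: high-high-low (e.g. 70, 70, 30) with probability
    ``p_highhighlow_given_diff``, else low-low-high (e.g. 30, 30, 70).  The
    forced schedule is a shuffled multiset of per-deck counts — (2,2,2) in
    the equal-information condition, a uniformly permuted (4,2,0) in the
    unequal one — and the horizon is geometric with mode at 6.
    """
    base = float(rng.choice(config.base_means))
    if rng.random() < config.p_equal_means:
        adj = float(rng.choice(config.adjustments))
        sign = rng.choice((-1.0, 1.0))
        means = np.full(N_DECKS, base + sign * adj)
    else:
        nonzero = [a for a in config.adjustments if a > 0]
        adj = float(rng.choice(nonzero))
        high, low = base + adj, base - adj
        if rng.random() < config.p_highhighlow_given_diff:
            means = np.array([high, high, low])
        else:
            means = np.array([low, low, high])
        means = rng.permutation(means)

    if rng.random() < config.p_unequal_info:
        condition = "unequal"
        counts = rng.permutation([4, 2, 0])
    else:
        condition = "equal"
        counts = np.full(N_DECKS, config.n_forced // N_DECKS)
    schedule = np.repeat(np.arange(N_DECKS), counts)
    rng.shuffle(schedule)

    return Game(
        game_id=int(game_id),
        gen_means=tuple(float(m) for m in means),
        info_condition=condition,
        forced_schedule=tuple(int(c) for c in schedule),
        horizon=_sample_horizon(config, rng),
    )


def make_session(config: TaskConfig, rng: np.random.Generator) -> list[Game]:
    """Generate ``config.n_games`` independent games."""
    return [make_game(config, gid, rng) for gid in range(config.n_games)]


def session_to_frame(session: list[Game]) -> pd.DataFrame:
    """Tabular view of a session (one row per game), round-trippable."""
    return pd.DataFrame(
        {
            "game_id": [g.game_id for g in session],
            "mean_0": [g.gen_means[0] for g in session],
            "mean_1": [g.gen_means[1] for g in session],
            "mean_2": [g.gen_means[2] for g in session],
            "info_condition": [g.info_condition for g in session],
            "forced_schedule": ["".join(map(str, g.forced_schedule)) for g in session],
            "horizon": [g.horizon for g in session],
        }
    )


def session_from_frame(frame: pd.DataFrame) -> list[Game]:
    """Inverse of :func:`session_to_frame`."""
    return [
        Game(
            game_id=int(row.game_id),
            gen_means=(float(row.mean_0), float(row.mean_1), float(row.mean_2)),
            info_condition=str(row.info_condition),
            forced_schedule=tuple(int(ch) for ch in str(row.forced_schedule)),
            horizon=int(row.horizon),
        )
        for row in frame.itertuples(index=False)
    ]
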