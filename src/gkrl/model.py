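"""The gamma-knowledge reinforcement-learning (gkRL) agent.

gkRL learns an expected reward value Q per deck with a delta rule,

    Q_{t+1}(c) = Q_t(c) + alpha * (R_t - Q_t(c)),

tracks how often each deck has been sampled within the current game, and
converts the cumulative sample count n(c) into an information term

    I_t(c) = n(c) ** gamma,

so the subjective value entering choice is V(c) = Q(c) - omega * I(c).
A positive information weight omega makes heavily sampled decks less
attractive (directed exploration toward the unknown); gamma bends the
count-to-information mapping (concave for gamma < 1).  Choices are softmax
in V with inverse temperature beta.  The "standard" baseline is the same
model with omega fixed at 0 (and gamma irrelevant).

Fitting scores only the first free choice of each game: the agent's state
is replayed through the game's six forced trials and the likelihood of the
observed first free choice is evaluated under the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import N_DECKS, Game, TaskConfig, draw_payoff

__all__ = [
    "AgentParams",
    "AgentState",
    "OptionValuation",
    "update_q",
    "info_value",
    "option_values",
    "choice_probabilities",
    "simulate_agent",
    "negative_log_likelihood",
    "GameArrays",
    "compile_trials",
    "nll_from_arrays",
    "q_after_forced",
]

#: Probability floor inside log() during likelihood evaluation.
PROB_FLOOR = 1e-12

#: Default initial expected reward value (midpoint of the 1..100 payoff scale).
Q0_DEFAULT = 50.0

TRIAL_COLUMNS = [
    "subject_id",
    "game_id",
    "trial_index",
    "phase",
    "choice",
    "payoff",
    "pre_count_0",
    "pre_count_1",
    "pre_count_2",
    "q_pre",
    "delta",
]


@dataclass(frozen=True)
class AgentParams:
    """gkRL parameters.

    alpha : learning rate, in (0, 1).
    beta : softmax inverse temperature, >= 0 (per point of value).
    omega : information weight; positive values penalise well-sampled decks.
    gamma : information exponent, > 0.
    model_tag : "gkrl" or "standard" (omega forced to 0, gamma unused).
    q0 : initial expected reward value for every deck, in points.
    """

    alpha: float
    beta: float
    omega: float = 0.0
    gamma: float = 1.0
    model_tag: str = "gkrl"
    q0: float = Q0_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.model_tag not in ("gkrl", "standard"):
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        if self.model_tag == "standard" and self.omega != 0.0:
            object.__setattr__(self, "omega", 0.0)

    @property
    def n_free_params(self) -> int:
        """Free parameters entering the fit (4 for gkRL, 2 for standard RL)."""
        return 2 if self.model_tag == "standard" else 4


@dataclass
class AgentState:
    """Learned values and per-deck sample counts within one game."""

    q: np.ndarray
    counts: np.ndarray

    @classmethod
    def fresh(cls, q0: float = Q0_DEFAULT) -> "AgentState":
        return cls(q=np.full(N_DECKS, float(q0)), counts=np.zeros(N_DECKS, dtype=int))


@dataclass(frozen=True)
class OptionValuation:
    """Per-deck information value, final value and choice probabilities."""

    i_val: np.ndarray
    v: np.ndarray
    probs: np.ndarray


def update_q(q_c: float, alpha: float, payoff: float) -> tuple[float, float]:
    """Delta-rule update of one deck's expected reward value.

    Returns ``(q_next, delta)`` with ``delta = payoff - q_c`` the prediction
    error and ``q_next = q_c + alpha * delta``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    delta = payoff - q_c
    return q_c + alpha * delta, delta


def info_value(count: float, gamma: float) -> float:
    """Information accumulated from ``count`` samples: count ** gamma."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return float(count) ** gamma


def option_values(state: AgentState, params: AgentParams) -> OptionValuation:
    """Evaluate V(c) = Q(c) - omega * counts(c)**gamma for every deck."""
    i_val = np.asarray(state.counts, dtype=float) ** params.gamma
    v = state.q - params.omega * i_val
    return OptionValuation(i_val=i_val, v=v, probs=choice_probabilities(v, params.beta))


def choice_probabilities(v: np.ndarray, beta: float) -> np.ndarray:
    """Softmax over option values with inverse temperature ``beta``.

    Max-subtracted for numerical stability; sums to 1 exactly up to float
    rounding, uniform at beta = 0.
    """
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("option values must be finite")
    z = beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def simulate_agent(
    params: AgentParams,
    session: list[Game],
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Simulate one subject playing a full session.

    Per game the state resets to Q0 and zero counts; forced trials follow the
    game's schedule, then ``horizon`` free choices are sampled from the
    softmax.  Learning continues through every observed payoff, including
    free trials after the first.  Returns a trial table with one row per
    trial (columns ``TRIAL_COLUMNS``), deck indices 0-based.
    """
    rows: list[tuple] = []
    for game in session:
        state = AgentState.fresh(params.q0)
        schedule = list(game.forced_schedule) + [None] * game.horizon
        for t, forced_choice in enumerate(schedule):
            if forced_choice is None:
                phase = "free"
                valuation = option_values(state, params)
                choice = int(rng.choice(N_DECKS, p=valuation.probs))
            else:
                phase = "forced"
                choice = int(forced_choice)
            payoff = draw_payoff(
                game.gen_means[choice], config.payoff_sd, config.payoff_bounds, rng
            )
            q_pre = float(state.q[choice])
            rows.append(
                (
                    subject_id,
                    game.game_id,
                    t,
                    phase,
                    choice,
                    payoff,
                    int(state.counts[0]),
                    int(state.counts[1]),
                    int(state.counts[2]),
                    q_pre,
                    payoff - q_pre,
                )
            )
            state.q[choice], _ = update_q(q_pre, params.alpha, payoff)
            state.counts[choice] += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# Likelihood machinery.  Fitting evaluates the NLL thousands of times, so the
# trial table is compiled once into padded per-game arrays and the NLL is a
# closed-form vectorised function of the parameters.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GameArrays:
    """Per-game arrays for vectorised first-free-choice likelihoods.

    forced_choices / forced_payoffs : (G, n_forced)
    first_free_choice : (G,) deck index of the first free choice
    pre_counts : (G, 3) forced sample counts per deck
    """

    forced_choices: np.ndarray
    forced_payoffs: np.ndarray
    first_free_choice: np.ndarray
    pre_counts: np.ndarray

    @property
    def n_games(self) -> int:
        return self.forced_choices.shape[0]


def compile_trials(trials: pd.DataFrame) -> GameArrays:
    """Extract, per game, the forced history and the first free choice."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    forced = trials[trials["phase"] == "forced"]
    free = trials[trials["phase"] == "free"]
    first_free = free.loc[free.groupby("game_id")["trial_index"].idxmin()]
    game_ids = first_free["game_id"].to_numpy()
    if len(game_ids) == 0:
        raise ValueError("trial table contains no free choices")

    n_forced = forced.groupby("game_id").size()
    if n_forced.nunique() != 1:
        raise ValueError("games differ in forced-trial count")
    nf = int(n_forced.iloc[0])

    forced_sorted = forced.sort_values(["game_id", "trial_index"])
    fc = forced_sorted["choice"].to_numpy().reshape(-1, nf)
    fp = forced_sorted["payoff"].to_numpy(dtype=float).reshape(-1, nf)
    forced_game_ids = forced_sorted["game_id"].to_numpy()[::nf]
    order = {g: i for i, g in enumerate(forced_game_ids)}
    idx = np.array([order[g] for g in game_ids])

    pre_counts = np.zeros((len(game_ids), N_DECKS), dtype=int)
    for d in range(N_DECKS):
        pre_counts[:, d] = (fc[idx] == d).sum(axis=1)

    return GameArrays(
        forced_choices=fc[idx],
        forced_payoffs=fp[idx],
        first_free_choice=first_free["choice"].to_numpy(),
        pre_counts=pre_counts,
    )


def q_after_forced(arrays: GameArrays, alpha: float, q0: float = Q0_DEFAULT) -> np.ndarray:
    """Q values per (game, deck) after replaying the forced trials."""
    G = arrays.n_games
    q = np.full((G, N_DECKS), float(q0))
    rows = np.arange(G)
    for t in range(arrays.forced_choices.shape[1]):
        c = arrays.forced_choices[:, t]
        q_c = q[rows, c]
        q[rows, c] = q_c + alpha * (arrays.forced_payoffs[:, t] - q_c)
    return q


def nll_from_arrays(params: AgentParams, arrays: GameArrays) -> float:
    """Negative log likelihood of the first free choices, vectorised."""
    q = q_after_forced(arrays, params.alpha, params.q0)
    v = q - params.omega * arrays.pre_counts.astype(float) ** params.gamma
    z = params.beta * v
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    p_chosen = probs[np.arange(arrays.n_games), arrays.first_free_choice]
    return float(-np.sum(np.log(np.maximum(p_chosen, PROB_FLOOR))))


def negative_log_likelihood(params: AgentParams, trials: pd.DataFrame) -> float:
    """NLL of each game's first free choice under ``params``.

    The agent's state evolves from Q0 through the game's forced trials only;
    free trials after the first do not enter the likelihood.
    """
    return nll_from_arrays(params, compile_trials(trials))


def as_standard(params: AgentParams) -> AgentParams:
    """Reward-only baseline with the same alpha/beta."""
    return replace(params, omega=0.0, model_tag="standard")
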