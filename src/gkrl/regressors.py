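"""Model-derived regressors at the first free choice of each game.

For a fitted subject, learning is replayed through each game's forced trials
and every quantity entering the study-style design matrices is evaluated at
the moment of the first free choice:

- exp_reward: Q of the chosen deck.
- rel_reward: Q_chosen minus the mean Q of the unchosen decks.
- info_gain: -I_chosen = -(count_chosen ** gamma); larger (closer to 0) for
  less-sampled decks.  omega is deliberately excluded — the modulator is the
  functional form of information, not its subjective weighting.
- rel_info: -(I_chosen - mean I_unchosen), signed consistently with info_gain.
- asd: across-option SD of the three Q values (a choice-difficulty proxy).
- switch_stay: 0 if the first free choice repeats the final forced choice.
- default_flag: "default" if the chosen deck is (one of) the least sampled,
  i.e. the most informative option.
- highest_flag: "highest" if the chosen deck has the highest mean forced
  payoff in that game.
- auxiliary reward codings: max_q, min_q, mean_q, chosen_minus_second.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AgentParams, GameArrays, compile_trials, q_after_forced

__all__ = ["build_first_choice_regressors", "standardize_columns"]


def build_first_choice_regressors(
    trials: pd.DataFrame, params: AgentParams
) -> pd.DataFrame:
    """One row per game, all regressors evaluated at the first free choice.

    ``trials`` must contain every game's forced trials; learning replays from
    Q0 with the subject's fitted ``params``.
    """
    arrays: GameArrays = compile_trials(trials)
    q = q_after_forced(arrays, params.alpha, params.q0)  # (G, 3)
    counts = arrays.pre_counts.astype(float)
    i_val = counts**params.gamma
    G = arrays.n_games
    rows = np.arange(G)
    chosen = arrays.first_free_choice

    q_chosen = q[rows, chosen]
    i_chosen = i_val[rows, chosen]
    unchosen_mask = np.ones((G, 3), dtype=bool)
    unchosen_mask[rows, chosen] = False
    q_unchosen = q[unchosen_mask].reshape(G, 2)
    i_unchosen = i_val[unchosen_mask].reshape(G, 2)

    # mean forced payoff per (game, deck); never-sampled decks have no mean
    payoff_sums = np.zeros((G, 3))
    for d in range(3):
        payoff_sums[:, d] = np.where(
            arrays.forced_choices == d, arrays.forced_payoffs, 0.0
        ).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_payoff = np.where(counts > 0, payoff_sums / np.maximum(counts, 1), -np.inf)

    last_forced = arrays.forced_choices[:, -1]
    min_count = counts.min(axis=1)
    q_sorted = np.sort(q, axis=1)

    free_trials = trials[trials["phase"] == "free"]
    game_ids = (
        free_trials.loc[free_trials.groupby("game_id")["trial_index"].idxmin()]
        .sort_values("game_id")["game_id"]
        .to_numpy()
    )

    return pd.DataFrame(
        {
            "game_id": game_ids,
            "choice": chosen,
            "exp_reward": q_chosen,
            "rel_reward": q_chosen - q_unchosen.mean(axis=1),
            "info_gain": -i_chosen,
            "rel_info": -(i_chosen - i_unchosen.mean(axis=1)),
            "asd": q.std(axis=1, ddof=1),
            "switch_stay": (chosen != last_forced).astype(int),
            "default_flag": np.where(
                counts[rows, chosen] == min_count, "default", "nodefault"
            ),
            "highest_flag": np.where(
                mean_payoff[rows, chosen] >= mean_payoff.max(axis=1), "highest", "lower"
            ),
            "sample_count": counts[rows, chosen].astype(int),
            "max_q": q.max(axis=1),
            "min_q": q.min(axis=1),
            "mean_q": q.mean(axis=1),
            "chosen_minus_second": q_chosen - np.where(
                q_chosen >= q_sorted[:, 2], q_sorted[:, 1], q_sorted[:, 2]
            ),
        }
    )


def standardize_columns(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Return a copy with each named column scaled to mean 0, SD 1 (ddof=1).

    Raises on constant columns (their scale is undefined), naming the column.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to standardize")
    out = table.copy()
    for name in columns:
        col = out[name].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {name!r} is constant; cannot standardize")
        out[name] = (col - col.mean()) / sd
    return out
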