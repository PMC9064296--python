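"""Bayesian value of information via grid beliefs and pruned forward search.

A learner's belief about one deck is a joint discrete posterior over the
deck's Gaussian mean mu and standard deviation sigma.  The default grid uses
mu in 10-point increments from 5 to 95 (10 bins) and sigma the integers 1..25,
updated by Bayes' rule with a Normal likelihood after each observed payoff.

The long-run value of choosing a deck is computed by forward tree search:
the value of a state is its expected immediate payoff plus the maximum
expected value of the continuation, with outcomes discretised to the mu-bin
centres and low-probability branches pruned.  The *instrumental* value of
information of a deck is the difference between this Bayes value and the
same search run while withholding the belief update after the root choice —
i.e. the part of a choice's worth that comes from what its outcome teaches
the learner, in points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .task import N_DECKS, Game, TaskConfig, draw_payoff, make_game

__all__ = [
    "BeliefGrid",
    "SearchConfig",
    "uniform_prior",
    "update_belief",
    "pretrain_global_prior",
    "predictive_outcome_distribution",
    "tree_search_value",
    "instrumental_information",
    "instrumental_for_session",
]


def _default_mu_grid(n_bins: int = 10, lo: float = 0.0, hi: float = 100.0) -> np.ndarray:
    """Bin centres of ``n_bins`` equal-width reward bins over [lo, hi]."""
    width = (hi - lo) / n_bins
    return lo + width * (np.arange(n_bins) + 0.5)


@dataclass(frozen=True)
class BeliefGrid:
    """Joint discrete belief P(mu, sigma) for one deck.

    weights has shape (len(mu_grid), len(sigma_grid)), nonnegative, sums to 1.
    """

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.mu_grid), len(self.sigma_grid)):
            raise ValueError("weights shape does not match the grids")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-10):
            raise ValueError("weights must be a normalized distribution")

    def mu_marginal(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def expected_mu(self) -> float:
        """Expected mean reward, numerically integrated over sigma."""
        return float(self.mu_marginal() @ self.mu_grid)


@dataclass(frozen=True)
class SearchConfig:
    """Forward-search settings: depth, pruning threshold, outcome bins."""

    depth: int = 6
    prune_threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 <= self.prune_threshold < 1.0):
            raise ValueError("prune_threshold must lie in [0, 1)")


def uniform_prior(
    mu_grid: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
) -> BeliefGrid:
    """Uniform joint prior; default 10 mu bins (5..95) x 25 sigma values (1..25)."""
    mu = _default_mu_grid() if mu_grid is None else np.asarray(mu_grid, dtype=float)
    sigma = (
        np.arange(1.0, 26.0) if sigma_grid is None else np.asarray(sigma_grid, dtype=float)
    )
    w = np.full((len(mu), len(sigma)), 1.0 / (len(mu) * len(sigma)))
    return BeliefGrid(mu_grid=mu, sigma_grid=sigma, weights=w)


def update_belief(grid: BeliefGrid, payoff: float) -> BeliefGrid:
    """Bayes update after observing ``payoff``: posterior ∝ prior × N(payoff | mu, sigma)."""
    like = norm.pdf(payoff, grid.mu_grid[:, None], grid.sigma_grid[None, :])
    post = grid.weights * like
    total = post.sum()
    if not (total > 0) or not np.isfinite(total):
        raise ValueError("posterior has no mass: payoff incompatible with the grid")
    return BeliefGrid(grid.mu_grid, grid.sigma_grid, post / total)


def pretrain_global_prior(
    config: TaskConfig,
    rng: np.random.Generator,
    n_games: int = 10,
    grid: BeliefGrid | None = None,
) -> BeliefGrid:
    """Global prior from forced-choice payoffs of ``n_games`` random games.

    Emulates pre-experiment exposure: the learner sees every forced-trial
    payoff of freshly generated games and updates a single global belief,
    which later seeds each game's per-deck beliefs.
    """
    g = uniform_prior() if grid is None else grid
    for i in range(n_games):
        game = make_game(config, i, rng)
        for choice in game.forced_schedule:
            payoff = draw_payoff(
                game.gen_means[choice], config.payoff_sd, config.payoff_bounds, rng
            )
            g = update_belief(g, payoff)
    return g


def _bin_integrals(grid: BeliefGrid) -> np.ndarray:
    """P(outcome bin | mu, sigma) for every mu-bin outcome.

    Shape (n_bins, n_mu, n_sigma).  Bin b spans [b - w/2, b + w/2) with w the
    grid spacing; the extreme bins absorb the open tails so columns sum to 1.
    """
    mu = grid.mu_grid
    sigma = grid.sigma_grid
    half = (mu[1] - mu[0]) / 2.0 if len(mu) > 1 else np.inf
    lo = mu - half
    hi = mu + half
    lo[0] = -np.inf
    hi[-1] = np.inf
    z_hi = (hi[:, None, None] - mu[None, :, None]) / sigma[None, None, :]
    z_lo = (lo[:, None, None] - mu[None, :, None]) / sigma[None, None, :]
    return norm.cdf(z_hi) - norm.cdf(z_lo)


def predictive_outcome_distribution(grid: BeliefGrid) -> np.ndarray:
    """Predictive probability of each mu-bin outcome under the belief."""
    return np.tensordot(_bin_integrals(grid), grid.weights, axes=([1, 2], [0, 1]))


class _TreeSearch:
    """Shared state for one forward search (bin model cached per grid shape)."""

    def __init__(self, grids: list[BeliefGrid], search: SearchConfig):
        self.search = search
        self.mu = grids[0].mu_grid
        self.bins = _bin_integrals(grids[0])  # (n_bins, n_mu, n_sigma)
        self.weights = [g.weights for g in grids]

    def _predictive(self, w: np.ndarray) -> np.ndarray:
        return np.tensordot(self.bins, w, axes=([1, 2], [0, 1]))

    def _posterior(self, w: np.ndarray, bin_idx: int) -> np.ndarray:
        # coherent discrete update: the likelihood of an in-tree outcome is
        # its bin probability, so value-of-information nonnegativity is exact
        post = w * self.bins[bin_idx]
        return post / post.sum()

    def option_value(
        self,
        weights: list[np.ndarray],
        option: int,
        depth_left: int,
        path_prob: float,
        update_current: bool,
    ) -> float:
        pred = self._predictive(weights[option])
        immediate = float(pred @ self.mu)
        if depth_left <= 1:
            return immediate

        keep = path_prob * pred >= self.search.prune_threshold
        if not keep.any():
            keep = pred == pred.max()  # keep the modal outcome rather than none
        p_kept = pred[keep] / pred[keep].sum()
        value = 0.0
        for bin_idx, p in zip(np.flatnonzero(keep), p_kept):
            if update_current:
                new_weights = list(weights)
                new_weights[option] = self._posterior(weights[option], bin_idx)
            else:
                # counterfactual: the outcome is received (and its branch
                # probability is real) but teaches the learner nothing
                new_weights = weights
            cont = max(
                self.option_value(new_weights, c, depth_left - 1, path_prob * p, True)
                for c in range(len(weights))
            )
            value += p * (float(self.mu[bin_idx]) + cont)
        return value


def tree_search_value(
    grids: list[BeliefGrid],
    search: SearchConfig,
    update_first: bool = True,
) -> np.ndarray:
    """Long-run value of choosing each option, by pruned forward search.

    The value of a state is its expected immediate payoff plus the maximum
    expected continuation value; outcomes are the mu-bin centres with
    probabilities from the predictive distribution; branches whose path
    probability falls below ``prune_threshold`` are dropped and the
    surviving sibling outcomes renormalised.  With ``update_first=False``
    the outcome of the root choice does not update beliefs (the
    reward-without-information counterfactual); deeper choices update
    normally.
    """
    ts = _TreeSearch(grids, search)
    return np.array(
        [
            ts.option_value(ts.weights, c, search.depth, 1.0, update_first)
            for c in range(len(grids))
        ]
    )


def instrumental_information(
    grids: list[BeliefGrid], search: SearchConfig
) -> np.ndarray:
    """Instrumental value of information per option, in points.

    Bayes value with root-outcome updating minus the value when the root
    outcome is withheld from learning.  Zero at depth 1 (the information has
    no future use) and nonnegative in general.
    """
    with_info = tree_search_value(grids, search, update_first=True)
    without = tree_search_value(grids, search, update_first=False)
    return with_info - without


def instrumental_for_session(
    trials: pd.DataFrame,
    session: list[Game],
    global_prior: BeliefGrid,
    search: SearchConfig,
) -> pd.DataFrame:
    """Per-game instrumental information at the first free choice.

    Per game the three per-deck beliefs start from the global prior, are
    updated by that game's forced payoffs (each payoff updates only the
    chosen deck's belief), and the pruned search is run at the first
    free-choice state.  Returns one row per game with per-option values and
    the value of the deck actually chosen.
    """
    forced = trials[trials["phase"] == "forced"]
    free = trials[trials["phase"] == "free"]
    first_free = free.loc[free.groupby("game_id")["trial_index"].idxmin()]
    chosen = dict(zip(first_free["game_id"], first_free["choice"]))

    rows = []
    for game in session:
        if game.game_id not in chosen:
            continue
        grids = [global_prior] * N_DECKS
        hist = forced[forced["game_id"] == game.game_id].sort_values("trial_index")
        for choice, payoff in zip(hist["choice"], hist["payoff"]):
            grids = list(grids)
            grids[choice] = update_belief(grids[choice], float(payoff))
        info = instrumental_information(grids, search)
        c = int(chosen[game.game_id])
        rows.append(
            {
                "game_id": game.game_id,
                "info_0": info[0],
                "info_1": info[1],
                "info_2": info[2],
                "choice": c,
                "info_chosen": info[c],
            }
        )
    return pd.DataFrame(rows)
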