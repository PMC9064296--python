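"""Instrumental value of information via Bayesian forward search.

A grid Bayesian learner (joint belief over each deck's Gaussian mean and SD)
is pretrained on the forced choices of 10 random games, then placed at the
first free choice of a game where one deck was sampled four times, another
twice, and one never.  The pruned forward search values each deck with and
without learning from the upcoming outcome; the difference is the
instrumental information — how many points the observation itself is worth
over the remaining horizon.
"""

import numpy as np

from gkrl import (
    SearchConfig,
    TaskConfig,
    instrumental_information,
    pretrain_global_prior,
    tree_search_value,
    update_belief,
)
from gkrl.task import draw_payoff

rng = np.random.default_rng(5)
config = TaskConfig()
prior = pretrain_global_prior(config, rng, n_games=10)

# forced phase of an unequal-information game: deck 0 four times (mean ~58),
# deck 1 twice (mean ~42), deck 2 never observed
grids = [prior, prior, prior]
for deck, mean in [(0, 58), (0, 58), (0, 58), (0, 58), (1, 42), (1, 42)]:
    payoff = draw_payoff(mean, config.payoff_sd, config.payoff_bounds, rng)
    grids[deck] = update_belief(grids[deck], payoff)

# exact enumeration (no pruning) keeps the tiny values bias-free; production
# runs at depth 6 rely on the default prune_threshold of 0.001 for speed
search = SearchConfig(depth=3, prune_threshold=0.0)
value = tree_search_value(grids, search)
info = instrumental_information(grids, search)

print("deck  samples  long-run value  instrumental information (points)")
for deck, n in zip(range(3), (4, 2, 0)):
    print(f"{deck:4d}  {n:7d}  {value[deck]:14.2f}  {info[deck]:12.3f}")

print(
    "\nThe never-sampled deck carries the most instrumental information: its\n"
    "outcome can redirect the remaining choices.  The values are small in\n"
    "absolute terms because the pooled pretraining prior is already quite\n"
    "confident about what decks in general pay; what matters downstream is\n"
    "their variation across trials (they enter GLMs standardized).  At\n"
    "search depth 1 every instrumental value would be exactly zero —\n"
    "information only has value when there are future choices to inform."
)
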