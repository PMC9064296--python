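"""Generate a synthetic cohort and inspect its task structure.

Builds 4 simulated subjects, each playing 32 three-deck games (6 forced
choices, then 1-6 free choices), with behaviour from gkRL agents at random
parameters, and prints the structural summary a behavioural analyst would
check first: game counts, information conditions, and how often the first
free choice takes the never-sampled deck.
"""

import numpy as np

from gkrl import CohortSpec, TaskConfig, generate_cohort

spec = CohortSpec(n_subjects=4, task=TaskConfig(n_games=32), seed=7)
tables, manifest = generate_cohort(spec)

print("true generating parameters:")
print(manifest[["subject_id", "alpha", "beta", "omega", "gamma"]].round(3).to_string(index=False))

trials = tables[0]
free = trials[trials.phase == "free"]
first_free = free.loc[free.groupby("game_id").trial_index.idxmin()]
pre = first_free[["pre_count_0", "pre_count_1", "pre_count_2"]].to_numpy()
unequal = pre.max(axis=1) == 4
chose_unsampled = (
    pre[np.arange(len(first_free)), first_free.choice.to_numpy()] == 0
)[unequal]

print(f"\nsubject 0: {trials.game_id.nunique()} games, {len(trials)} trials")
print(f"unequal-information games: {unequal.sum()} of {len(first_free)}")
print(
    "first free choice took the never-sampled deck in "
    f"{100 * chose_unsampled.mean():.1f}% of unequal games"
)
print(
    "\nA strongly information-seeking agent (omega well above 0) picks the\n"
    "unsampled deck far more often than the 33% a random chooser would."
)
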