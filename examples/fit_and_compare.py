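"""Fit gkRL and the reward-only baseline, compare by BIC and exceedance probability.

Simulates 8 information-seeking subjects, fits both models to each subject's
first free choices, and runs fixed-effect (summed BIC) and random-effects
(exceedance probability) model comparison.  Because the data were generated
by gkRL with substantial information weights, both comparisons should favour
gkRL decisively.
"""

import numpy as np

from gkrl import CohortSpec, TaskConfig, exceedance_probability, fit_mle, generate_cohort

spec = CohortSpec(n_subjects=8, task=TaskConfig(n_games=96), seed=21)
tables, manifest = generate_cohort(spec)

rng = np.random.default_rng(1)
evidence = np.empty((len(tables), 2))
summed = {"gkrl": 0.0, "standard": 0.0}
print("subject   BIC(gkRL)  BIC(standard)")
for i, trials in enumerate(tables):
    fits = {tag: fit_mle(trials, tag, n_starts=6, rng=rng) for tag in ("gkrl", "standard")}
    for j, tag in enumerate(("gkrl", "standard")):
        evidence[i, j] = -fits[tag].bic / 2.0
        summed[tag] += fits[tag].bic
    print(f"{i:7d}   {fits['gkrl'].bic:9.1f}  {fits['standard'].bic:13.1f}")

print(f"\nfixed effect — summed BIC: gkRL {summed['gkrl']:.1f}, standard {summed['standard']:.1f}")
bms = exceedance_probability(evidence, rng, model_names=("gkrl", "standard"))
xp = bms.exceedance_probabilities
print(f"random effects — exceedance probabilities: gkRL {xp[0]:.3f}, standard {xp[1]:.3f}")
print(
    "\nLower summed BIC and xp near 1 both indicate the cohort is better\n"
    "explained by a model that values information on top of reward."
)
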