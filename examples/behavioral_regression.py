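"""Behavioural signature of information seeking in exploitation rates.

Per subject, the exploit target of each game is the deck with the highest
mean forced-phase payoff.  A logistic regression predicts whether the first
free choice takes that target from (a) its mean forced payoff and (b) how
often it was sampled; per-subject slopes are t-tested across subjects.
Information-seeking agents exploit less when the best deck is already well
sampled, so the "sample" beta comes out negative.
"""

import numpy as np

from gkrl import CohortSpec, TaskConfig, behavioral_choice_regression, generate_cohort

spec = CohortSpec(n_subjects=10, task=TaskConfig(n_games=96), seed=13)
tables, _ = generate_cohort(spec)
results = behavioral_choice_regression(tables)

print("predictor        mean beta        t       df        p")
for name, res in results.items():
    print(f"{name:15s}  {res.mean_beta:+9.3f}  {res.t:+7.2f}  {res.df:7d}  {res.p:.2e}")

print(
    "\nA positive reward beta (exploit more when the target pays more) with a\n"
    "negative sample beta (exploit less when the target is over-sampled) is\n"
    "the joint reward + information signature this task was built to elicit."
)
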