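"""Parameter recovery: can fitting identify the parameters that made the data?

Draws 10 parameter sets from the documented plausible ranges, simulates a
full session per set, refits each simulated subject on first free choices,
and correlates true with recovered values.  (The package's headline run uses
20 subjects; 10 keeps this demo quick.)
"""

import numpy as np

from gkrl import DEFAULT_PARAM_RANGES, TaskConfig, parameter_recovery, sample_agent_params

rng = np.random.default_rng(2)
sets = [sample_agent_params(DEFAULT_PARAM_RANGES, rng) for _ in range(10)]
report = parameter_recovery(sets, TaskConfig(), rng)

print("parameter   Pearson r (true vs recovered)")
for name in ("alpha", "beta", "omega", "gamma"):
    print(f"{name:9s}   {report.pearson_r[name]:+.3f}")

print(
    "\nCorrelations well above zero mean the first-free-choice likelihood\n"
    "carries enough signal to identify each parameter; alpha and beta are\n"
    "typically recovered best, the information weight and exponent are\n"
    "noisier because they only separate on unequal-information games."
)
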