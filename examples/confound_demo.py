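"""The shared-variance confound, and how serial orthogonalization removes it.

Two value signals — relative reward and information gain — are computed by
construction by independent systems of the same agent, yet they correlate
across trials because choices depend on both.  Regressing each "system's"
activity on each signal (63 simulated runs, group t-tests on the betas)
shows spurious cross-effects; orthogonalizing the regressors removes them
while leaving each system's own effect intact.
"""

import numpy as np

from gkrl import confound_experiment

# a little measurement noise on the "system activity" keeps the own-signal
# regressions from being trivially exact (beta = 1 with infinite t)
for ortho in (False, True):
    label = "serially orthogonalized" if ortho else "confounded (raw regressors)"
    results = confound_experiment(
        n_runs=63, rng=np.random.default_rng(11), orthogonalize=ortho, noise_sd=0.3
    )
    print(f"\n{label}:")
    print("system        contrast      mean beta        t        p")
    for (system, contrast), res in sorted(results.items()):
        print(
            f"{system:12s}  {contrast:12s}  {res.mean_beta:+9.4f}  {res.t:+8.2f}  {res.p:.2e}"
        )

print(
    "\nWithout orthogonalization the cross cells (reward system ~ information\n"
    "signal and vice versa) show solid group effects (beta ~ 0.17) although\n"
    "the systems are independent by construction.  After serial\n"
    "orthogonalization the cross betas collapse by two orders of magnitude\n"
    "and their p-values become ordinary null draws (values below 0.05 occur\n"
    "at the usual 5% rate), while the own-signal effects are untouched —\n"
    "recovering the true architecture of two independent value systems."
)
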