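# gkrl — reward value vs information value in explore–exploit choice

When people (or agents) choose among uncertain options, two distinct
quantities make an option attractive: the reward it is expected to pay, and
the information its outcome would provide about options that are still
poorly known. Because the same choices are driven by both, the two signals
are correlated across trials — and any analysis that regresses on one of
them in isolation will attribute part of the other's influence to it. This
package implements, end to end and on synthetic data, the computational
toolkit for separating the two:

- a three-armed bandit **task** in which six forced choices per game control
  how often each deck has been sampled — either evenly (2, 2, 2) or unevenly
  (4, 2, 0) — before 1–6 free choices with a hidden horizon;
- the **gkRL model** (gamma-knowledge reinforcement learning), which learns
  deck values `Q` by a delta rule, `Q ← Q + α(R − Q)`, accumulates sample
  counts `n` into an information term `I = n^γ`, and chooses by softmax over
  `V = Q − ωI` with inverse temperature β — a positive information weight ω
  makes well-sampled decks less attractive (directed exploration);
- a **Bayesian forward search** that prices the *instrumental* value of
  information in points: a grid belief over each deck's Gaussian mean and SD
  is propagated through a pruned decision tree with and without learning
  from the next outcome, and the difference is what that observation is
  worth over the remaining horizon;
- **fitting and comparison** machinery: multi-start regularized maximum
  likelihood on first free choices, posterior-mean estimates for parameter
  recovery, BIC, and random-effects model selection with exceedance
  probabilities;
- **regressor construction** (relative reward, information gain, and the
  associated categorical codings) plus the **confound diagnostics**: serial
  orthogonalization, the 63-run two-system demonstration, VIF-based
  regressor pruning, and the behavioural exploitation regression;
- a **synthetic cohort generator** so the whole pipeline runs and is tested
  without any external data.

It is intended for computational cognitive scientists who want to simulate,
fit and stress-test information-bonus models of exploration, and for anyone
who needs a concrete, runnable demonstration of the shared-variance
(orthogonalization) problem in model-based regression analyses.

## Worked example

Simulate eight information-seeking subjects, fit both gkRL and a
reward-only baseline to each subject's first free choices, and compare the
models (`examples/fit_and_compare.py`):

```text
subject   BIC(gkRL)  BIC(standard)
      0       113.0          129.9
      1       122.4          140.0
      2       109.9          109.1
      ...
fixed effect — summed BIC: gkRL 989.7, standard 1154.3
random effects — exceedance probabilities: gkRL 0.962, standard 0.038
```

The summed BIC favours gkRL by ~165 points even though it pays a
two-parameter penalty per subject, and the random-effects comparison puts
the probability that gkRL is the more frequent model in the population at
0.96 — the cohort's behaviour carries a clear information signature.
Subject 2 shows the penalty working in the other direction: an individual
whose choices happen to be explainable by reward alone.

Parameter recovery on ten simulated subjects
(`examples/parameter_recovery.py`):

```text
parameter   Pearson r (true vs recovered)
alpha       +0.742
beta        +0.930
omega       +0.831
gamma       +0.733
```

Each correlation compares the parameters that generated a subject's
behaviour with those recovered by refitting; values well above zero mean
128 first free choices identify the parameter. Learning rate and
temperature are usually recovered best; the information weight and exponent
only separate on unequal-information games and are noisier.

The other examples each demonstrate one capability in a few lines:
`simulate_cohort.py` (task structure and information-seeking rates),
`confound_demo.py` (the spurious cross-system effects and their removal by
serial orthogonalization), `instrumental_information.py` (the forward
search pricing an observation in points), and `behavioral_regression.py`
(the positive-reward / negative-sample-count signature of joint reward and
information drives).

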