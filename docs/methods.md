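# Methods

This package implements a complete, synthetic-data-driven pipeline for
dissociating reward value from information value in sequential choice: a
three-armed bandit task with controlled forced sampling, the
gamma-knowledge reinforcement-learning (gkRL) agent, a Bayesian
forward-search computation of the instrumental value of information,
maximum-likelihood model fitting with parameter and model recovery, the
model-derived regressors used in GLM-style analyses, and the
shared-variance (serial-orthogonalization) confound diagnostics.

## Task model

Each game offers three decks paying integer points in [1, 100]. Payoffs are
Gaussian with SD 8 points around a per-deck generative mean that is fixed
within a game; draws are rounded to the nearest integer and clipped into
[1, 100]. Means are built from a base of 30 or 50 points shifted by 0, 4,
12 or 20 points, so a single draw is uninformative about the mean and all
means lie in [10, 70]. Half the games (configurable) give all decks the
same mean; in the rest two decks share a mean and the third differs —
high-high-low (e.g. 70, 70, 30) in a quarter of those, low-low-high
otherwise (the deck-to-mean assignment is uniformly permuted).

A game begins with six forced choices that control information exposure:
(2, 2, 2) across decks in the equal-information condition or a uniformly
permuted (4, 2, 0) in the unequal one (each with probability 0.5,
configurable). It continues with 1–6 free choices; the horizon is drawn
with weight proportional to `decay^(6 − h)` (default decay 0.5), making 6
the modal horizon while shorter games occur — the agent is never told the
horizon. A session is 128 independent games.

Unstated details of the original procedure that needed a choice: the
equal/unequal game proportion (50/50), the horizon law (geometric shape
with mode at the longest horizon, matching a verbal "exponentially
inversely distributed" description), integer rounding before clipping, and
the uniform permutation of forced counts over decks. All are configurable
on `TaskConfig`.

## The gkRL agent

Per deck `c` the agent learns an expected reward value by a delta rule,

    Q_{t+1}(c) = Q_t(c) + α (R_t − Q_t(c)),

and tracks the number of times the deck was sampled this game. The sample
count enters choice as an information term `I_t(c) = n_t(c)^γ` with γ > 0
controlling the curvature of the count-to-information mapping. The value
driving choice is

    V(c) = Q(c) − ω I(c),

so ω > 0 devalues well-sampled decks (directed exploration); ω's sign is
deliberately unconstrained, encoding information seeking vs avoidance.
Choices are softmax in V with inverse temperature β ≥ 0 (per point). The
reward-only baseline ("standard") is the same model with ω fixed at 0 and
two free parameters (α, β).

`I` is computed from the counts *before* the current choice, so a
never-sampled deck always has `I = 0`. Initial values start at Q₀ = 50, the
payoff-scale midpoint: in unequal games one deck is never sampled during
the forced phase and retains Q₀ at the first free choice, so a neutral
midpoint is the least committal prior (configurable). During simulation the
agent keeps learning through all free trials; fitting scores only the first
free choice of each game (see below), which is where the forced-sampling
design guarantees that reward experience and information exposure are
decoupled.

## Likelihood and estimation

The likelihood of a subject is the product over games of the softmax
probability of the observed first free choice, with the agent's state
replayed from Q₀ through that game's forced trials. Later free choices do
not enter the likelihood. A floor of 1e−12 inside the log guards against
numerical zeros. The per-subject negative log likelihood is evaluated from
precompiled per-game arrays, which makes one evaluation a handful of
vectorised operations over a (games × decks) array.

Optimization runs in an unconstrained space — logistic transform for α,
softplus for β and γ, identity for ω — with multi-start Nelder-Mead
(default 10 starts plus a polish restart from the best point). The
likelihood is combined with weak fixed priors:

| parameter | prior | rationale |
|---|---|---|
| α | Beta(1.5, 1.5) | keeps estimates off the α→0 boundary |
| β | Gamma(2, scale 0.15) | excludes the degenerate β→∞ ridge |
| ω | Normal(0, 10) | symmetric; spans ±(points-scale) weights |
| γ | Gamma(2, scale 0.75) | soft upper control of the ω/γ trade-off |

These priors exist because this model family has two classic degeneracies
that plain maximum likelihood falls into whenever a subject's choices are
weakly diagnostic (low β): the (α→0, β→∞) ridge on which only the product
of learning rate and temperature is identified, and the ω/γ ridge along
constant `ω·count^γ` (with counts taking only the values 0, 2 and 4 at the
first free choice, only the two penalties `ω·2^γ` and `ω·4^γ` are directly
identified). The priors are weak enough to leave well-identified subjects
at their maximum-likelihood values; BIC is always computed from the raw
(unpenalized) NLL at the optimum.

Two point estimates are provided. The posterior mode (MAP) is the fast
default. For parameter recovery the package uses posterior means, computed
by a coordinate-wise adaptive random-walk Metropolis chain started at the
MAP (24 000 iterations, 4 000 burn-in with proposal-scale adaptation toward
~40% acceptance, thinning 5; means taken in natural parameter space).
Posterior means are the minimum-mean-squared-error estimator and behave
much better than the mode for weakly identified subjects, whose posteriors
are broad: the mean shrinks them to a stable centre instead of leaving them
at an arbitrary ridge point. Hierarchical (empirical-Bayes) estimation
would be the next step up and is deliberately out of scope.

## Parameter and model recovery

Parameter recovery draws generating parameters uniformly from the
documented plausible ranges (α ∈ [0.1, 0.9], β ∈ [0.02, 0.3],
ω ∈ [0.5, 10], γ ∈ [0.3, 1.5]), simulates a full 128-game session per
subject, refits on first free choices, and reports the Pearson correlation
between generating and recovered values per parameter. With 20-subject
cohorts these correlations are themselves noisy statistics (the sampling
SE of r at n = 20 is roughly 0.1–0.15); across independent cohorts they
centre near 0.75 (α), 0.82 (β), 0.67 (ω) and 0.65 (γ). The β range
includes near-random choosers (β ≈ 0.02) whose parameters are essentially
unidentifiable from 128 choices; they attenuate all four correlations,
ω and γ especially, which also only separate on unequal-information games.

Model comparison uses BIC = 2·NLL + k·ln(n) with n the number of scored
first free choices (128) and k the number of free parameters (4 gkRL,
2 standard), summed over subjects for the fixed-effect contrast. The
random-effects comparison is the standard variational scheme over model
frequencies: starting from a uniform Dirichlet prior, iterate
digamma-weighted responsibilities of each subject's −BIC/2 evidence to
convergence (1e−8), then estimate exceedance probabilities — the posterior
probability that each model is the most frequent — by Monte-Carlo sampling
from the fitted Dirichlet (10⁶ draws).

## Instrumental value of information

The learner's belief about one deck is a joint discrete distribution over
the deck's Gaussian mean μ (10-point bins centred 5…95 by default) and SD
σ (integers 1…25), updated by Bayes' rule with the Normal likelihood of
each observed payoff. A global prior is pretrained by pooling the forced
payoffs of 10 generated games into a single belief; per game, the three
per-deck beliefs are reset to this global prior and updated only by that
game's forced outcomes for the sampled decks.

The long-run value of choosing a deck is computed by forward tree search.
Outcomes inside the tree are discretised to the μ-bin centres, with
probabilities from the predictive distribution (bin integrals of the
Normal CDF under the belief, open tails absorbed into the extreme bins).
The value of a state is its expected immediate payoff plus the maximum
expected continuation value over options; at the leaves the value is the
expected payoff, i.e. the belief's expected mean. In-tree belief updates
use the bin-integral likelihood of the observed outcome bin — the coherent
discrete-model update — which makes the nonnegativity of the value of
information an exact theorem for the unpruned search. Branches whose path
probability falls below 0.001 (configurable) are pruned and the surviving
sibling outcome probabilities renormalised, so continuation values remain
proper expectations.

Instrumental information of a deck is the difference between the search
value with belief updating at the root choice and a counterfactual run in
which the root outcome is received (branch probabilities unchanged) but
teaches the learner nothing; deeper levels update normally in both runs.
Traversing identical branch structures in both passes matters: collapsing
the root branch in the counterfactual makes pruning asymmetric between the
two passes and can produce spurious negative values of several tenths of a
point. At depth 1 instrumental information is exactly zero — information
only has value while future choices remain. Default search depth is 6 (the
maximum horizon) regardless of the realized horizon; tests and examples
use depths 2–3, where the exhaustive (unpruned) search is affordable and
is verified against an independently written enumeration oracle.

Two properties of the discretisation are worth knowing. First, pruning is
an approximation: with the default threshold the pruned and exact values
can differ by a few hundredths of a point, and pruned instrumental values
can dip marginally below zero. Second, pooled pretraining concentrates the
global belief to a posterior roughly 2.5 points wide — narrower than a
10-point μ cell — so the coarse default grid starts each game nearly
saturated and its instrumental values become small and noisy. The
discretisation-robustness check (per-state instrumental information at 10
vs 20 μ bins, Pearson r > 0.9) therefore starts from the uniform prior,
which isolates the search's sensitivity to grid resolution from this
saturation effect.

## Model-derived regressors

For a fitted subject, learning is replayed through each game's forced
trials and all regressors are evaluated at the first free choice:
`exp_reward` (Q of the chosen deck), `rel_reward` (Q chosen minus mean Q
unchosen; for three decks identically 1.5·(Q_c − mean Q)), `info_gain`
(−I of the chosen deck — ω is deliberately excluded, the modulator is the
functional form of information, not its subjective weight), `rel_info`
(−(I chosen − mean I unchosen), signed like `info_gain`), the
across-option SD of Q (sample SD, n−1 denominator, as everywhere in the
package), switch/stay vs the final forced choice, a default flag (chosen
deck is among the least sampled, i.e. most informative), a highest flag
(chosen deck has the highest mean forced payoff), and auxiliary reward
codings (max, min, mean Q, chosen minus best other). Standardization
(mean 0, SD 1, n−1) is applied per column on request and refuses constant
columns by name.

## Confound diagnostics

The two-system demonstration simulates an agent whose reward signal
(RelReward) and information signal (InfoGain) are computed by independent
parts of the model, yet correlate across trials because both drive the same
choices. Per run (63 runs by default, parameters drawn from the cohort
ranges), each "system's activity" is the standardized model variable
itself; each activity is regressed on each signal and the slope betas are
t-tested against zero across runs. With raw regressors the cross
regressions are group-significant — apparent overlap between systems.
Serially orthogonalizing the competitor signal against the system's own
signal (residualizing later columns on earlier ones after mean-centering)
removes the cross effects while own effects survive. With standardized
regressors the cross beta equals the sample correlation of the two
signals; under the default conditions that correlation is positive,
because Q₀ = 50 exceeds the ≈ 40-point average payoff, so
information-driven choices of never-sampled decks carry above-average
relative reward. Its sign flips if Q₀ is set at or below the typical
payoff level — the confound's existence, not its direction, is the robust
phenomenon.

VIF-based pruning reproduces the collinearity workflow for competing
reward definitions: per subject design, columns are standardized and a
small Normal(0, 0.01) noise is injected (to break exact collinearity and
make VIFs finite and ordinal), VIF_i = 1/(1 − R²_i) is averaged across
subjects, and the highest-VIF column is removed iteratively until all
average VIFs fall below 5.

The behavioural regression tests the joint influence of reward and
information on exploitation: per subject, the exploit target of a game is
the deck with the highest mean forced payoff; a logistic regression
predicts whether the first free choice takes that target from the target's
mean forced payoff and its forced sample count (standardized per subject),
and per-subject slopes are t-tested across subjects. Information-seeking
cohorts show a negative sample beta — they exploit less when the best deck
is already well known. Perfectly separated subjects fall back to a small
L2 (ridge) penalty, flagged in the return value. The original mixed-model
version of this analysis (random slopes over subjects) is approximated by
this summary-statistics approach throughout; full mixed models are out of
scope.

## What the synthetic cohorts do and do not emulate

Cohorts reproduce the task's structure (20 subjects, 128 games, forced
schedules, payoff process, hidden horizons) and generate behaviour from
gkRL agents at uniformly drawn parameters. They do not emulate reaction
times, scanner timing, motion, session breaks, fatigue, or any BOLD-level
signal; "system activity" in the confound experiment is the model variable
itself, not a noisy haemodynamic observation (an optional noise flag
exists). Passing tests therefore demonstrate the computational pipeline's
correctness and the logic of the confound argument — not that any specific
brain region behaves this way. Real human parameters are also unlikely to
be uniform on the documented ranges; recovery correlations measured here
are conditional on that generator.

## Numerical choices

Softmax is max-subtracted; probabilities sum to 1 within 1e−12. Belief
grids renormalise after every update and refuse observations with no
posterior mass. The likelihood floor is 1e−12; Nelder-Mead tolerances are
1e−5/1e−6 (1e−6/1e−8 for the polish); the variational Dirichlet iteration
converges at 1e−8. Ties in the default flag (equal-information games) count
as "default"; the highest flag compares mean forced payoffs with unsampled
decks excluded (−∞). Serial orthogonalization mean-centres all named
columns first, so intercepts absorb means; rank-deficient earlier blocks
are an error. Seeds: every stochastic routine takes a numpy Generator;
given the same generator state, sessions, simulations, fits, chains and
Dirichlet sampling are bit-reproducible.

## Known limitations

- Depth-6 unpruned search is infeasible (branching 30 per level); the
  default pruning makes it tractable but approximate, and deep searches on
  broad beliefs remain slow (tens of seconds per state).
- Recovery quality is bounded by the information in 128 first free choices;
  correlations for ω and γ in particular are attenuated by subjects with
  low β, and no estimator choice can undo that.
- The BIC-based evidence is a proxy; Laplace or bridge estimates would
  sharpen the random-effects comparison but are out of scope.
- The pooled global prior saturates coarse belief grids (see above); a
  mixture-over-decks pretraining would preserve heterogeneity but would be
  a different model of pre-task learning than pooled updating.
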