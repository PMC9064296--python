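"""Regression and collinearity machinery for the shared-variance analyses.

The core demonstration: when two signals (relative reward and information
gain) are generated by *independent* systems but correlate across trials,
regressing each system's activity on the other signal yields spurious
group-significant effects; serially orthogonalizing the regressors removes
the cross-talk while preserving each system's own effect.  This module
provides the serial orthogonalization, OLS/logistic fits, the group-level
one-sample t-test, the 63-run simulation experiment, VIF-based regressor
pruning with noise injection, and the behavioral exploitation regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .model import AgentParams, compile_trials, q_after_forced, simulate_agent
from .regressors import build_first_choice_regressors, standardize_columns
from .task import TaskConfig, make_session

__all__ = [
    "GroupTestResult",
    "serial_orthogonalize",
    "ols_betas",
    "logistic_fit",
    "one_sample_ttest",
    "confound_experiment",
    "vif_prune",
    "behavioral_choice_regression",
]


@dataclass(frozen=True)
class GroupTestResult:
    """One-sample t-test of per-subject (or per-run) betas against zero."""

    mean_beta: float
    t: float
    p: float
    df: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def serial_orthogonalize(design: pd.DataFrame, order: list[str]) -> pd.DataFrame:
    """Serially orthogonalize named columns; earlier columns win shared variance.

    All columns in ``order`` are mean-centered; each is then replaced by its
    residual after OLS projection onto all *earlier* columns in ``order``.
    Later regressors therefore only explain variance the earlier ones cannot.
    Columns outside ``order`` are left untouched.
    """
    out = design.copy()
    if len(set(order)) != len(order):
        raise ValueError("orthogonalization order contains duplicates")
    for name in order:
        out[name] = out[name].astype(float) - out[name].astype(float).mean()
    for i, name in enumerate(order):
        if i == 0:
            continue
        earlier = out[order[:i]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(earlier) < earlier.shape[1]:
            raise ValueError(
                f"earlier block {order[:i]} is rank deficient; cannot project"
            )
        y = out[name].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(earlier, y, rcond=None)
        out[name] = y - earlier @ coef
    return out


def ols_betas(y: np.ndarray, design: pd.DataFrame):
    """OLS with intercept; returns the fitted statsmodels results object."""
    X = sm.add_constant(np.asarray(design, dtype=float), has_constant="add")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is singular")
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def logistic_fit(y: np.ndarray, design: pd.DataFrame, ridge_alpha: float = 1.0):
    """Maximum-likelihood logistic regression (IRLS) with intercept.

    Returns the coefficient vector [intercept, slopes...].  Under perfect
    separation the ML estimate diverges; the fit then falls back to a small
    L2 (ridge) penalty so coefficients stay finite, which is reported via the
    second return value.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(np.asarray(design, dtype=float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(tol=1e-8, maxiter=200)
        separated = not np.all(np.isfinite(res.bse)) or np.any(
            np.abs(res.params) > 1e3
        )
    except Exception:
        separated = True
    if separated:
        res = model.fit_regularized(alpha=ridge_alpha / len(y), L1_wt=0.0)
        return np.asarray(res.params), True
    return np.asarray(res.params), False


def one_sample_ttest(values: np.ndarray) -> GroupTestResult:
    """Two-sided one-sample t-test of ``values`` against zero."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values")
    if np.std(values, ddof=1) == 0:
        raise ValueError("values have zero variance; t is undefined")
    t, p = sps.ttest_1samp(values, 0.0)
    return GroupTestResult(mean_beta=float(values.mean()), t=float(t), p=float(p), df=n - 1)


# ---------------------------------------------------------------------------
# The two-system confound experiment.
# ---------------------------------------------------------------------------


def confound_experiment(
    param_ranges: dict[str, tuple[float, float]] | None = None,
    n_runs: int = 63,
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    orthogonalize: bool = False,
    noise_sd: float = 0.0,
) -> dict[tuple[str, str], GroupTestResult]:
    """Simulate the two-system shared-variance demonstration.

    Per run, a gkRL agent with parameters drawn from ``param_ranges`` plays a
    full session; the relative-reward and information-gain series at first
    free choices are standardized and treated as the activity of a reward
    system and an information system.  Each system's activity is regressed on
    each signal — raw regressors when ``orthogonalize`` is False, serially
    orthogonalized ones (the predicted signal's competitor first) when True —
    and the slope betas are t-tested against zero across runs.

    Returns a dict keyed by ``(system, contrast)`` with system and contrast
    in {"reward", "information"}.  ``noise_sd`` optionally adds Gaussian
    noise to the system activities.
    """
    from .cohort import DEFAULT_PARAM_RANGES, sample_agent_params

    ranges = dict(DEFAULT_PARAM_RANGES) if param_ranges is None else param_ranges
    config = TaskConfig() if config is None else config
    rng = np.random.default_rng(0) if rng is None else rng

    signal_of = {"reward": "rel_reward", "information": "info_gain"}
    betas: dict[tuple[str, str], list[float]] = {
        (sys_, con) for sys_ in signal_of for con in signal_of
    }
    betas = {key: [] for key in betas}

    for _ in range(n_runs):
        params = sample_agent_params(ranges, rng, model_tag="gkrl")
        session = make_session(config, rng)
        trials = simulate_agent(params, session, config, rng)
        reg = build_first_choice_regressors(trials, params)
        reg = standardize_columns(reg, ["rel_reward", "info_gain"])

        for system, sys_col in signal_of.items():
            activity = reg[sys_col].to_numpy()
            if noise_sd > 0:
                activity = activity + rng.normal(0.0, noise_sd, size=len(activity))
            for contrast, con_col in signal_of.items():
                if orthogonalize and contrast != system:
                    # the cross regressor enters only via variance the
                    # system's own signal cannot explain
                    design = serial_orthogonalize(
                        reg[["rel_reward", "info_gain"]], [sys_col, con_col]
                    )
                    x = design[[con_col]]
                else:
                    x = reg[[con_col]]
                res = ols_betas(activity, x)
                betas[(system, contrast)].append(float(res.params[1]))

    return {key: one_sample_ttest(np.asarray(vals)) for key, vals in betas.items()}


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_i = 1 / (1 - R^2) of column i regressed on the remaining columns."""
    n, k = X.shape
    out = np.empty(k)
    for i in range(k):
        others = np.delete(X, i, axis=1)
        others = np.column_stack([np.ones(n), others])
        y = X[:, i]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[i] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def vif_prune(
    subject_designs: list[pd.DataFrame],
    threshold: float = 5.0,
    noise_sd: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[dict[str, float]]]:
    """Iteratively drop the highest-VIF column until all average VIFs < threshold.

    Per subject design, columns are standardized and a small Gaussian noise
    (sd ``noise_sd``) is injected to break exact collinearity; VIFs are then
    averaged across subjects.  Returns the retained column names and the
    per-iteration average-VIF history (the removed column is the max entry of
    each history row).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    columns = list(subject_designs[0].columns)
    if len(columns) < 3:
        raise ValueError("need at least three columns to prune")

    noisy: list[pd.DataFrame] = []
    for design in subject_designs:
        std = standardize_columns(design, list(design.columns))
        arr = std.to_numpy(dtype=float)
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
        noisy.append(pd.DataFrame(arr, columns=design.columns))

    retained = list(columns)
    history: list[dict[str, float]] = []
    while len(retained) >= 2:
        avg = np.mean([_vifs(d[retained].to_numpy(dtype=float)) for d in noisy], axis=0)
        record = dict(zip(retained, avg))
        history.append(record)
        if np.nanmax(avg) < threshold:
            break
        retained.pop(int(np.nanargmax(avg)))
    return retained, history


def behavioral_choice_regression(
    cohort_tables: list[pd.DataFrame],
) -> dict[str, GroupTestResult]:
    """Group test of reward- and information-driven exploitation.

    Per subject and game, the exploit target is the deck with the highest
    mean forced-phase payoff; the dependent variable is whether the first
    free choice selects it.  Predictors (standardized per subject) are the
    target's mean forced payoff ("highest_reward") and the number of times it
    was sampled during the forced phase ("sample").  Per-subject logistic
    slopes are t-tested against zero across subjects.  Information seekers
    avoid over-sampled targets, so a positive information drive shows up as a
    negative group beta on "sample".
    """
    if len(cohort_tables) < 2:
        raise ValueError("need at least two subjects")

    slopes = {"highest_reward": [], "sample": []}
    for trials in cohort_tables:
        arrays = compile_trials(trials)
        counts = arrays.pre_counts.astype(float)
        payoff_sums = np.zeros_like(counts)
        for d in range(3):
            payoff_sums[:, d] = np.where(
                arrays.forced_choices == d, arrays.forced_payoffs, 0.0
            ).sum(axis=1)
        mean_payoff = np.where(counts > 0, payoff_sums / np.maximum(counts, 1), -np.inf)
        target = np.argmax(mean_payoff, axis=1)
        g = np.arange(arrays.n_games)
        y = (arrays.first_free_choice == target).astype(float)
        design = pd.DataFrame(
            {
                "highest_reward": mean_payoff[g, target],
                "sample": counts[g, target],
            }
        )
        design = standardize_columns(design, list(design.columns))
        coefs, _ = logistic_fit(y, design)
        slopes["highest_reward"].append(coefs[1])
        slopes["sample"].append(coefs[2])

    return {name: one_sample_ttest(np.asarray(vals)) for name, vals in slopes.items()}
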