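"""Synthetic cohorts: simulated subjects with the study's task structure.

A cohort emulates the experiment's shape — 20 subjects, 128 games each,
three decks, six forced then 1–6 free choices — with behaviour generated by
gkRL agents at parameters drawn uniformly from documented ranges.  The
default ranges keep the softmax on the 1–100 point payoff scale out of
saturation (beta small because values are in points) and span clearly
information-seeking to weakly information-seeking agents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TRIAL_COLUMNS, AgentParams, simulate_agent
from .task import N_DECKS, TaskConfig, make_session

__all__ = [
    "DEFAULT_PARAM_RANGES",
    "CohortSpec",
    "sample_agent_params",
    "generate_cohort",
    "write_trial_table",
    "load_trial_table",
]

DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.1, 0.9),
    "beta": (0.02, 0.3),
    "omega": (0.5, 10.0),
    "gamma": (0.3, 1.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """How to build a synthetic cohort."""

    n_subjects: int = 20
    task: TaskConfig = field(default_factory=TaskConfig)
    param_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES)
    )
    generating_model: str = "gkrl"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.generating_model not in ("gkrl", "standard"):
            raise ValueError(f"unknown generating_model {self.generating_model!r}")
        for name, (lo, hi) in self.param_ranges.items():
            if lo > hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


def sample_agent_params(
    ranges: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    model_tag: str = "gkrl",
) -> AgentParams:
    """Independent uniform draws per parameter; standard agents get omega=0."""
    draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    if model_tag == "standard":
        return AgentParams(
            alpha=draws["alpha"], beta=draws["beta"], model_tag="standard"
        )
    return AgentParams(model_tag="gkrl", **draws)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Generate one trial table per subject plus a parameter manifest.

    Per subject: a fresh session from the task generator, behaviour from
    :func:`gkrl.model.simulate_agent` at sampled parameters.  The manifest
    records subject id, the true parameters and the spec seed, so recovery
    studies can compare against ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    tables: list[pd.DataFrame] = []
    manifest_rows = []
    for sid in range(spec.n_subjects):
        params = sample_agent_params(spec.param_ranges, rng, spec.generating_model)
        session = make_session(spec.task, rng)
        tables.append(simulate_agent(params, session, spec.task, rng, subject_id=sid))
        manifest_rows.append(
            {
                "subject_id": sid,
                "alpha": params.alpha,
                "beta": params.beta,
                "omega": params.omega,
                "gamma": params.gamma,
                "model": spec.generating_model,
                "seed": spec.seed,
            }
        )
    return tables, pd.DataFrame(manifest_rows)


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as tab-separated text with the documented header."""
    trials.to_csv(path, sep="\t", index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial table written by :func:`write_trial_table`.

    Checks the schema and the structural invariants: integer payoffs in
    [1, 100], 0-based deck indices, phases in {forced, free}, and per-trial
    pre-counts that are nonnegative and sum to the trial index.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns and c not in ("q_pre", "delta")]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")

    if not table["payoff"].between(1, 100).all():
        bad = table.loc[~table["payoff"].between(1, 100), "payoff"].iloc[0]
        raise ValueError(f"payoff out of range [1, 100]: {bad}")
    if (table["payoff"] != table["payoff"].astype(int)).any():
        raise ValueError("payoffs must be integers")
    if not table["choice"].isin(range(N_DECKS)).all():
        raise ValueError(f"deck indices must be 0..{N_DECKS - 1}")
    if not table["phase"].isin(["forced", "free"]).all():
        raise ValueError("phase must be 'forced' or 'free'")

    pre = table[["pre_count_0", "pre_count_1", "pre_count_2"]].to_numpy()
    if (pre < 0).any():
        raise ValueError("pre-counts must be nonnegative")
    if not (pre.sum(axis=1) == table["trial_index"].to_numpy()).all():
        raise ValueError("pre-counts must sum to the trial index")
    return table
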