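"""End-to-end orchestration: cohort -> labeled trajectories -> estimated
POMDP -> solved policy -> retrospective evaluation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Patient
from .estimation import (
    BinningScheme,
    SparseDataWarning,
    build_binning,
    estimate_observation_model,
    estimate_transitions,
)
from .evaluation import EvaluationReport, evaluate_transitions, kfold_split, per_state_policy_table
from .solver import (
    AlphaVectorPolicy,
    PomdpModel,
    default_reward_vector,
    perseus_solve,
    sample_beliefs,
)
from .states import (
    N_ACTIONS,
    OBSERVATION_VITALS,
    OTHER_ACTION_INDEX,
    NoActionError,
    StateLabel,
    VitalsSnapshot,
    encode_action,
)

__all__ = [
    "SolverConfig",
    "labeled_transition_triples",
    "snapshots_by_state",
    "build_model",
    "train_policy",
    "run_holdout",
    "run_cross_validation",
    "robustness_curve",
]


@dataclass
class SolverConfig:
    """Knobs for model building and Perseus solving."""

    gamma: float = 0.95
    laplace: float = 0.0  # uniform transition pseudo-count; 0 = pure frequencies
    shrinkage: float = 10.0  # pseudo-counts toward the state's marginal row
    n_beliefs: int = 60
    horizon: int = 30
    max_stages: int = 30
    tolerance: Optional[float] = None  # default: 1e-3 * max|R|
    seed: int = 42
    reward_overrides: Optional[dict] = None
    empirical_observations: bool = False


def _dynamics_action(drugs) -> int:
    try:
        return encode_action(drugs).index
    except NoActionError:
        return OTHER_ACTION_INDEX


def labeled_transition_triples(patients: Sequence[Patient]) -> list[tuple[int, int, int]]:
    """(state, action, next state) per consecutive snapshot pair per patient.

    The action is the antibiotic set administered in the interval; intervals
    without antibiotics fold into the catch-all action.
    """
    triples = []
    for patient in patients:
        labels = patient.labels()
        for i in range(len(labels) - 1):
            a = _dynamics_action(patient.timepoints[i].antibiotics)
            triples.append((int(labels[i]), a, int(labels[i + 1])))
    return triples


def snapshots_by_state(patients: Sequence[Patient]) -> dict[StateLabel, list[VitalsSnapshot]]:
    """Group non-terminal snapshots by their assigned state label."""
    out: dict[StateLabel, list[VitalsSnapshot]] = {}
    for patient in patients:
        for tp in patient.timepoints:
            if tp.outcome is not None:
                continue
            out.setdefault(tp.label(), []).append(tp.vitals)
    return out


def build_model(
    patients: Sequence[Patient],
    config: Optional[SolverConfig] = None,
) -> tuple[PomdpModel, BinningScheme]:
    """Estimate T and O from a training cohort and assemble the POMDP.

    The initial belief is the empirical initial-state frequency of the
    training patients; rewards are the default per-state table (with any
    configured overrides).
    """
    config = config or SolverConfig()
    triples = labeled_transition_triples(patients)
    tm = estimate_transitions(
        triples, laplace=config.laplace, shrinkage=config.shrinkage
    )

    by_state = snapshots_by_state(patients)
    samples = {}
    for state, snaps in by_state.items():
        for vital in OBSERVATION_VITALS:
            vals = [getattr(v, vital) for v in snaps if getattr(v, vital) is not None]
            if vals:
                samples[(state, vital)] = vals
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SparseDataWarning)
        binning = build_binning(samples)
        om = estimate_observation_model(
            by_state, binning, empirical=config.empirical_observations
        )

    b0 = np.zeros(len(StateLabel))
    for patient in patients:
        labels = patient.labels()
        if labels:
            b0[int(labels[0])] += 1
    if b0.sum() == 0:
        b0[:] = 1.0
    b0 /= b0.sum()

    model = PomdpModel(
        T=tm.probabilities,
        O=om.dense(),
        R=default_reward_vector(config.reward_overrides),
        b0=b0,
        gamma=config.gamma,
        state_names=tuple(s.name for s in StateLabel),
    )
    model.validate(atol=1e-9)
    return model, binning


def train_policy(model: PomdpModel, config: Optional[SolverConfig] = None) -> AlphaVectorPolicy:
    """Sample beliefs (corners included) and run Perseus."""
    config = config or SolverConfig()
    beliefs = sample_beliefs(
        model,
        n=config.n_beliefs,
        horizon=config.horizon,
        seed=config.seed,
        include_corners=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return perseus_solve(
            model,
            beliefs,
            tolerance=config.tolerance,
            max_iterations=config.max_stages,
            seed=config.seed,
        )


def run_holdout(
    patients: Sequence[Patient],
    train_fraction: float = 2 / 3,
    config: Optional[SolverConfig] = None,
    run_tests: bool = True,
) -> EvaluationReport:
    """Single train/test split: estimate + solve on train, evaluate on test."""
    config = config or SolverConfig()
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(patients))
    n_train = max(1, int(round(train_fraction * len(patients))))
    train = [patients[i] for i in perm[:n_train]]
    test = [patients[i] for i in perm[n_train:]]
    model, binning = build_model(train, config)
    policy = train_policy(model, config)
    report = evaluate_transitions(test, policy, model, binning, run_tests=run_tests)
    report.policy_table = {
        s.name: str(a) for s, a in per_state_policy_table(policy, model).items()
    }
    return report


def run_cross_validation(
    patients: Sequence[Patient],
    k: int = 5,
    config: Optional[SolverConfig] = None,
) -> list[EvaluationReport]:
    """k-fold CV at patient level; one report per fold."""
    config = config or SolverConfig()
    index = {p.patient_id: p for p in patients}
    reports = []
    for train_ids, test_ids in kfold_split([p.patient_id for p in patients], k, config.seed):
        train = [index[i] for i in train_ids]
        test = [index[i] for i in test_ids]
        model, binning = build_model(train, config)
        policy = train_policy(model, config)
        report = evaluate_transitions(test, policy, model, binning)
        report.policy_table = {
            s.name: str(a) for s, a in per_state_policy_table(policy, model).items()
        }
        reports.append(report)
    return reports


def robustness_curve(
    patients: Sequence[Patient],
    fractions: Sequence[float],
    repeats: int = 10,
    config: Optional[SolverConfig] = None,
) -> list[dict]:
    """Followed-arm %-better vs training-set fraction.

    A fixed one-third of the patients is held out for testing; for each
    fraction, the two-thirds training pool is subsampled and the full
    estimate + solve + evaluate pipeline re-run ``repeats`` times (once for
    fraction 1.0, which is deterministic given the split).
    """
    config = config or SolverConfig()
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(patients))
    n_test = max(1, len(patients) // 3)
    test = [patients[i] for i in perm[:n_test]]
    pool = [patients[i] for i in perm[n_test:]]

    rows = []
    for f in fractions:
        n_sub = max(1, int(round(f * len(pool))))
        values = []
        n_repeats = 1 if f >= 1.0 else repeats
        for r in range(n_repeats):
            sub_idx = rng.choice(len(pool), size=n_sub, replace=False)
            train = [pool[i] for i in sub_idx]
            try:
                model, binning = build_model(train, config)
            except Exception:
                values.append(float("nan"))  # degenerate subsample
                continue
            policy = train_policy(model, config)
            report = evaluate_transitions(test, policy, model, binning, run_tests=False)
            values.append(report.percentages["followed"]["better"])
        arr = np.asarray(values, dtype=float)
        rows.append(
            {
                "fraction": float(f),
                "n_train": n_sub,
                "values": values,
                "mean_pct_better_followed": float(np.nanmean(arr)),
                "sd_pct_better_followed": float(np.nanstd(arr)),
            }
        )
    return rows
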