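"""Synthetic EHR cohorts with known ground truth.

Patients follow latent ten-state Markov dynamics with action-dependent
transitions; each live state emits state-conditional vitals, a blood-culture
Bernoulli signal and per-vital missingness.  The three "probable" states are
produced by deterministic missingness of the SIRS vitals, so the labeling
rules recover them exactly.  Trajectories absorb into death or dismissal or
truncate at a maximum length.

Scenarios:

* ``strong_signal`` — one designated drug combination strictly increases the
  probability of moving to a better state (full margin for the exact
  combination, half margin for any overlapping combination).
* ``null_signal`` — transitions are identical across actions, and the
  better/same/worse split is identical across live states (no confounding
  for the evaluation harness to pick up).
* ``paper_like`` — state mix loosely shaped toward a majority of mild and
  probable-SIRS states with rare septic shock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Patient, TimePoint
from .estimation import build_binning, estimate_transitions
from .states import (
    ABSORBING_STATES,
    N_ACTIONS,
    OBSERVATION_VITALS,
    SEVERITY_ORDER,
    TREATABLE_STATES,
    Culture,
    StateLabel,
    VitalsSnapshot,
    action_from_index,
    encode_action,
    severity_rank,
)

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "SCENARIOS",
    "BENEFICIAL_DRUGS",
    "make_scenario",
    "simulate_cohort",
    "recovery_experiment",
]

SCENARIOS = ("strong_signal", "null_signal", "paper_like")

#: The designated beneficial combination in the strong-signal scenario.
BENEFICIAL_DRUGS = frozenset({"VANCOMYCIN", "CEFTRIAXONE"})

#: Clinically plausible hard ranges used to clip emissions.
PLAUSIBLE_RANGES = {
    "temperature": (30.0, 43.0),
    "heart_rate": (20.0, 220.0),
    "respiratory_rate": (5.0, 60.0),
    "wbc": (500.0, 50000.0),
    "map": (30.0, 150.0),
    "sbp": (50.0, 250.0),
}

ALL_VITALS = ("temperature", "heart_rate", "respiratory_rate", "wbc", "map", "sbp")
SIRS_EMISSION_VITALS = ("temperature", "heart_rate", "respiratory_rate", "wbc")

# mean, sd per vital for "normal" and "inflamed" physiology
_NORMAL_VITALS = {
    "temperature": (37.0, 0.3),
    "heart_rate": (75.0, 6.0),
    "respiratory_rate": (14.0, 2.0),
    "wbc": (8000.0, 1200.0),
    "map": (90.0, 6.0),
    "sbp": (120.0, 8.0),
}
_SIRS_VITALS_PARAMS = {
    "temperature": (39.0, 0.3),
    "heart_rate": (112.0, 7.0),
    "respiratory_rate": (27.0, 2.5),
    "wbc": (15500.0, 1200.0),
    "map": (85.0, 5.0),
    "sbp": (112.0, 7.0),
}
_HYPOTENSIVE_BP = {"map": (55.0, 4.0), "sbp": (74.0, 5.0)}


def _emissions() -> dict[StateLabel, dict[str, tuple[float, float]]]:
    e: dict[StateLabel, dict[str, tuple[float, float]]] = {}
    e[StateLabel.NO_SIRS] = dict(_NORMAL_VITALS)
    e[StateLabel.SIRS] = dict(_SIRS_VITALS_PARAMS)
    e[StateLabel.SEPSIS] = dict(_SIRS_VITALS_PARAMS)
    e[StateLabel.SEPTIC_SHOCK] = {**_SIRS_VITALS_PARAMS, **_HYPOTENSIVE_BP}
    e[StateLabel.BACTEREMIA] = dict(_NORMAL_VITALS)
    e[StateLabel.PS] = dict(_NORMAL_VITALS)
    e[StateLabel.BPS] = dict(_NORMAL_VITALS)
    e[StateLabel.PSS] = {**_NORMAL_VITALS, **_HYPOTENSIVE_BP}
    return e


def _culture_rates() -> dict[StateLabel, float]:
    return {
        StateLabel.NO_SIRS: 0.01,
        StateLabel.SIRS: 0.01,
        StateLabel.SEPSIS: 0.99,
        StateLabel.SEPTIC_SHOCK: 0.99,
        StateLabel.BACTEREMIA: 0.99,
        StateLabel.PS: 0.0,
        StateLabel.BPS: 1.0,
        StateLabel.PSS: 1.0,
    }


def _missingness() -> dict[StateLabel, dict[str, float]]:
    """Probable states hide every SIRS vital; other states are complete."""
    miss: dict[StateLabel, dict[str, float]] = {
        s: {v: 0.0 for v in ALL_VITALS} for s in TREATABLE_STATES
    }
    for s in (StateLabel.PS, StateLabel.BPS, StateLabel.PSS):
        for v in SIRS_EMISSION_VITALS:
            miss[s][v] = 1.0
    return miss


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to simulate a cohort and score recovery against it."""

    scenario: str
    transition: np.ndarray  # (10, 32, 10)
    emissions: dict  # StateLabel -> vital -> (mean, sd)
    culture_rates: dict  # StateLabel -> P(positive)
    missingness: dict  # StateLabel -> vital -> P(missing)
    behavior_policy: np.ndarray  # (10, 32): action distribution per state
    initial_distribution: np.ndarray  # (10,)
    beneficial_action: Optional[int]
    seed: int

    def validate(self) -> None:
        if not np.allclose(self.transition.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("ground-truth transition rows must sum to 1")
        for s in ABSORBING_STATES:
            expected = np.zeros(len(StateLabel))
            expected[int(s)] = 1.0
            if not (self.transition[int(s)] == expected).all():
                raise ValueError(f"{s.name} must be absorbing")
        for state, vitals in self.emissions.items():
            for vital, (mean, _) in vitals.items():
                lo, hi = PLAUSIBLE_RANGES[vital]
                if not (lo <= mean <= hi):
                    raise ValueError(f"mean {vital} for {state} outside plausible range")


def _better_worse_targets(state: StateLabel) -> tuple[int, int]:
    """Adjacent better/worse states in the severity order (absorbing at the ends)."""
    rank = severity_rank(state)
    return int(SEVERITY_ORDER[rank - 1]), int(SEVERITY_ORDER[rank + 1])


def _row(state: StateLabel, p_better: float, p_worse: float) -> np.ndarray:
    row = np.zeros(len(StateLabel))
    better, worse = _better_worse_targets(state)
    row[better] += p_better
    row[worse] += p_worse
    row[int(state)] += 1.0 - p_better - p_worse
    return row


def make_scenario(name: str, seed: int = 42, margin: float = 0.5) -> GroundTruth:
    """Construct a ground truth for one of the named scenarios."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    S, A = len(StateLabel), N_ACTIONS
    T = np.zeros((S, A, S))
    beneficial: Optional[int] = None
    behavior = np.full((S, A), 1.0 / A)

    if name == "null_signal":
        # one action-independent row per live state; identical outcome split
        # across states so the pooled evaluation sees no confounding
        for state in TREATABLE_STATES:
            row = _row(state, p_better=0.30, p_worse=0.30)
            T[int(state), :, :] = row[None, :]
    else:
        beneficial_action = encode_action(BENEFICIAL_DRUGS)
        beneficial = beneficial_action.index
        base_better, base_worse = 0.20, 0.40
        if name == "paper_like":
            base_better, base_worse = 0.30, 0.25
        for state in TREATABLE_STATES:
            for a in range(A):
                act = action_from_index(a)
                if a == beneficial:
                    boost = margin
                elif act.drug_set & BENEFICIAL_DRUGS:
                    boost = margin / 2.0
                else:
                    boost = 0.0
                p_b = base_better + boost
                p_w = max(base_worse - boost, 0.05)
                total = p_b + p_w
                if total > 0.95:
                    p_b, p_w = 0.95 * p_b / total, 0.95 * p_w / total
                T[int(state), a, :] = _row(state, p_b, p_w)
        # behavior: epsilon-mixed so both evaluation arms are populated
        behavior = np.full((S, A), 0.5 / A)
        behavior[:, beneficial] += 0.5

    for s in ABSORBING_STATES:
        T[int(s), :, :] = 0.0
        T[int(s), :, int(s)] = 1.0
        behavior[int(s), :] = 1.0 / A

    init = np.zeros(S)
    if name == "paper_like":
        weights = {
            StateLabel.NO_SIRS: 0.40,
            StateLabel.PS: 0.35,
            StateLabel.SIRS: 0.10,
            StateLabel.BACTEREMIA: 0.05,
            StateLabel.BPS: 0.05,
            StateLabel.PSS: 0.025,
            StateLabel.SEPSIS: 0.02,
            StateLabel.SEPTIC_SHOCK: 0.005,
        }
        for state, w in weights.items():
            init[int(state)] = w
    else:
        for state in TREATABLE_STATES:
            init[int(state)] = 1.0 / len(TREATABLE_STATES)
    init /= init.sum()

    truth = GroundTruth(
        scenario=name,
        transition=T,
        emissions=_emissions(),
        culture_rates=_culture_rates(),
        missingness=_missingness(),
        behavior_policy=behavior,
        initial_distribution=init,
        beneficial_action=beneficial,
        seed=seed,
    )
    truth.validate()
    return truth


@dataclass
class SyntheticCohort:
    """Simulated patients plus their aligned latent state sequences."""

    patients: list[Patient]
    latent: dict[str, list[StateLabel]]
    truth: GroundTruth

    def __len__(self) -> int:
        return len(self.patients)


def _draw_snapshot(
    state: StateLabel, t: float, truth: GroundTruth, rng: np.random.Generator
) -> VitalsSnapshot:
    params = truth.emissions[state]
    miss = truth.missingness[state]
    values: dict[str, Optional[float]] = {}
    for vital in ALL_VITALS:
        if rng.random() < miss.get(vital, 0.0):
            values[vital] = None
        else:
            mean, sd = params[vital]
            lo, hi = PLAUSIBLE_RANGES[vital]
            values[vital] = float(np.clip(rng.normal(mean, sd), lo, hi))
    positive = rng.random() < truth.culture_rates[state]
    return VitalsSnapshot(
        timestamp=t,
        blood_culture=Culture.POSITIVE if positive else Culture.NEGATIVE,
        **values,
    )


def simulate_cohort(
    truth: GroundTruth,
    n_patients: int,
    max_length: int = 12,
    seed: int = 42,
) -> SyntheticCohort:
    """Simulate a cohort of patient trajectories under the ground truth.

    Each trajectory draws its initial state from the truth's initial
    distribution, then alternates behavior-policy actions and latent
    transitions, emitting a vitals snapshot per visited live state, until it
    absorbs (a terminal outcome row is appended) or hits ``max_length``.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    rng = np.random.default_rng(seed)
    S = len(StateLabel)
    patients: list[Patient] = []
    latent: dict[str, list[StateLabel]] = {}
    width = len(str(n_patients - 1))
    for p in range(n_patients):
        pid = f"P{p:0{width}d}"
        s = StateLabel(int(rng.choice(S, p=truth.initial_distribution)))
        states = [s]
        timepoints: list[TimePoint] = []
        t = 0.0
        for _ in range(max_length):
            snapshot = _draw_snapshot(s, t, truth, rng)
            a = int(rng.choice(N_ACTIONS, p=truth.behavior_policy[int(s)]))
            drugs = action_from_index(a).drug_set
            if not drugs:  # catch-all: an unlisted antibiotic
                drugs = frozenset({"OTHER_ANTIBIOTIC"})
            timepoints.append(TimePoint(snapshot, drugs))
            s = StateLabel(int(rng.choice(S, p=truth.transition[int(s), a])))
            states.append(s)
            t += 1.0
            if s in ABSORBING_STATES:
                outcome = "death" if s is StateLabel.DEATH else "dismissal"
                timepoints.append(
                    TimePoint(VitalsSnapshot(timestamp=t), frozenset(), outcome)
                )
                break
        patients.append(Patient(pid, timepoints))
        latent[pid] = states
    return SyntheticCohort(patients, latent, truth)


def recovery_experiment(
    truth: GroundTruth,
    n_grid: Sequence[int],
    seed: int = 42,
    max_length: int = 12,
) -> list[dict]:
    """Estimate models from cohorts of increasing size and score them.

    For each patient count ``n`` the cohort is simulated, labeled, and fed to
    the estimation module; the result row reports the mean total-variation
    distance of estimated transition rows (over observed, non-backed-off
    live rows) and the mean L1 distance of observation factors (over
    (state, vital) pairs with data) against the ground truth.
    """
    from .pipeline import labeled_transition_triples, snapshots_by_state

    rows = []
    for j, n in enumerate(n_grid):
        cohort = simulate_cohort(truth, n, max_length=max_length, seed=seed + j)
        triples = labeled_transition_triples(cohort.patients)
        tm = estimate_transitions(triples)

        tv_vals = []
        for state in TREATABLE_STATES:
            for a in range(N_ACTIONS):
                if not tm.backed_off[int(state), a]:
                    diff = tm.probabilities[int(state), a] - truth.transition[int(state), a]
                    tv_vals.append(0.5 * float(np.abs(diff).sum()))

        by_state = snapshots_by_state(cohort.patients)
        samples = {}
        for state, snaps in by_state.items():
            for vital in OBSERVATION_VITALS:
                vals = [getattr(v, vital) for v in snaps if getattr(v, vital) is not None]
                if vals:
                    samples[(state, vital)] = vals
        l1_vals = []
        if samples:
            import warnings as _warnings

            from .estimation import SparseDataWarning
            from scipy import stats as _stats

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", SparseDataWarning)
                binning = build_binning(samples)
            for (state, vital), factor in binning.factors.items():
                mean, sd = truth.emissions[state][vital]
                edges = binning.edges[vital]
                masses = np.diff(_stats.norm.cdf(edges, mean, sd))
                if masses.sum() <= 0:
                    continue
                masses = masses / masses.sum()
                l1_vals.append(float(np.abs(factor.probs - masses).sum()))

        rows.append(
            {
                "n_patients": int(n),
                "n_transitions": len(triples),
                "mean_tv_transition": float(np.mean(tv_vals)) if tv_vals else float("nan"),
                "mean_l1_observation": float(np.mean(l1_vals)) if l1_vals else float("nan"),
            }
        )
    return rows
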