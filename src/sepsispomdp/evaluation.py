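"""Retrospective evaluation of a solved antibiotic policy on held-out
trajectories.

For each test transition the running belief is maintained from the patient's
actual administered actions and observed vitals; the policy's recommended
action at the pre-transition belief is compared against what was actually
administered (a recommendation counts as followed when at least one of its
antibiotics was given).  Transitions split into followed / not-followed arms
and are classified better / same / worse against the severity order.
Enrichment of better outcomes in the followed arm is tested with one-sided
hypergeometric tail probabilities, Benjamini-Hochberg adjusted across the
family of tests emitted in one run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort import Patient
from .estimation import BinningScheme
from .solver import (
    AlphaVectorPolicy,
    InconsistentObservationError,
    PomdpModel,
    belief_update,
    extract_action,
)
from .states import (
    ABSORBING_STATES,
    NAMED_DRUGS,
    OTHER_ACTION_INDEX,
    AntibioticAction,
    Comparison,
    NoActionError,
    StateLabel,
    TREATABLE_STATES,
    action_from_index,
    compare_states,
    encode_action,
)

__all__ = [
    "TransitionRecord",
    "EvaluationReport",
    "policy_followed",
    "evaluate_transitions",
    "trajectory_statistics",
    "kfold_split",
    "enrichment_test",
    "bh_adjust",
    "per_state_policy_table",
]

ARMS = ("followed", "not_followed")
OUTCOMES = (Comparison.BETTER, Comparison.SAME, Comparison.WORSE)


def policy_followed(policy_action: AntibioticAction, administered: Iterable[str]) -> bool:
    """Whether an administered drug set follows the recommended action.

    A named-drug recommendation is followed iff at least one of its
    antibiotics was administered; the catch-all recommendation is followed
    iff any non-named antibiotic was given.
    """
    administered = set(administered)
    if policy_action.other_flag:
        return any(d not in NAMED_DRUGS for d in administered)
    return bool(policy_action.drug_set & administered)


@dataclass
class TransitionRecord:
    """One evaluated transition."""

    patient_id: str
    from_state: StateLabel
    to_state: StateLabel
    outcome: Comparison
    followed: bool
    policy_action: int
    administered: frozenset[str]


@dataclass
class EvaluationReport:
    """Aggregated followed vs not-followed outcome statistics."""

    transitions: list[TransitionRecord]
    counts: dict  # arm -> {better/same/worse -> int}
    percentages: dict  # arm -> {better/same/worse -> float}
    per_state_counts: dict  # (state name, arm) -> {outcome -> int}
    trajectory: dict  # arm -> bucket counts and denominators
    tests: list  # list of dicts: name, table, p_raw, p_adj
    policy_table: dict = field(default_factory=dict)  # state name -> drug string

    def arm_total(self, arm: str) -> int:
        return sum(self.counts[arm].values())

    def to_json(self, path=None) -> dict:
        payload = {
            "counts": self.counts,
            "percentages": self.percentages,
            "per_state_counts": {
                f"{state}|{arm}": dict(v) for (state, arm), v in self.per_state_counts.items()
            },
            "trajectory": self.trajectory,
            "tests": self.tests,
            "policy_table": self.policy_table,
            "n_transitions": len(self.transitions),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload

    def to_text(self) -> str:
        lines = ["Transitions by arm and outcome:"]
        header = f"{'arm':>14} {'better':>8} {'same':>8} {'worse':>8} {'total':>8}"
        lines.append(header)
        for arm in ARMS:
            c = self.counts[arm]
            total = sum(c.values())
            lines.append(
                f"{arm:>14} {c['better']:>8} {c['same']:>8} {c['worse']:>8} {total:>8}"
            )
            p = self.percentages[arm]
            lines.append(
                f"{'(%)':>14} {p['better']:>8.1f} {p['same']:>8.1f} {p['worse']:>8.1f}"
            )
        lines.append("")
        lines.append("Trajectory-level buckets (>=90% of a patient's arm transitions):")
        for arm in ARMS:
            t = self.trajectory[arm]
            lines.append(
                f"  {arm}: n={t['n_patients']}  >=90% better: {t['ge90_better']}"
                f"  >=90% better/same: {t['ge90_better_or_same']}"
                f"  >=90% worse: {t['ge90_worse']}"
            )
        if self.tests:
            lines.append("")
            lines.append("Hypergeometric enrichment tests (BH-adjusted):")
            for t in self.tests:
                lines.append(
                    f"  {t['name']}: p={t['p_raw']:.3g} adj={t['p_adj']:.3g}"
                )
        if self.policy_table:
            lines.append("")
            lines.append("Optimal drug combination per state (point-mass belief):")
            for state, drugs in self.policy_table.items():
                lines.append(f"  {state}: {drugs}")
        return "\n".join(lines)


def _action_index_for_dynamics(drugs: frozenset[str]) -> int:
    """Action used to propagate the belief / estimate T.

    The 32-action space has no explicit no-treatment action; intervals with
    no recorded antibiotics are folded into the catch-all index.
    """
    try:
        return encode_action(drugs).index
    except NoActionError:
        return OTHER_ACTION_INDEX


def evaluate_transitions(
    patients: Sequence[Patient],
    policy: AlphaVectorPolicy,
    model: PomdpModel,
    binning: BinningScheme,
    run_tests: bool = True,
) -> EvaluationReport:
    """Classify every test transition into arm and outcome buckets.

    The belief restarts at ``b0`` for each patient and is updated with the
    *actual* administered action and the next snapshot's observation code
    (the data records what actually happened, not the recommendation).
    """
    records: list[TransitionRecord] = []
    for patient in patients:
        labels = patient.labels()
        if len(labels) < 2:
            continue
        b = model.b0.copy()
        for i in range(len(labels) - 1):
            tp = patient.timepoints[i]
            nxt = patient.timepoints[i + 1]
            rec_action, _, _ = extract_action(policy, b)
            followed = policy_followed(action_from_index(rec_action), tp.antibiotics)
            records.append(
                TransitionRecord(
                    patient.patient_id,
                    labels[i],
                    labels[i + 1],
                    compare_states(labels[i], labels[i + 1]),
                    followed,
                    rec_action,
                    frozenset(tp.antibiotics),
                )
            )
            if nxt.outcome is not None:
                break  # absorbing; no further transitions for this patient
            a = _action_index_for_dynamics(frozenset(tp.antibiotics))
            z = binning.encode(nxt.vitals).index
            try:
                b, _ = belief_update(b, a, z, model)
            except InconsistentObservationError:
                b = model.b0.copy()

    counts = {arm: {o.value: 0 for o in OUTCOMES} for arm in ARMS}
    per_state: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        arm = "followed" if r.followed else "not_followed"
        counts[arm][r.outcome.value] += 1
        key = (r.from_state.name, arm)
        per_state.setdefault(key, {o.value: 0 for o in OUTCOMES})[r.outcome.value] += 1

    percentages = {}
    for arm in ARMS:
        total = sum(counts[arm].values())
        percentages[arm] = {
            o.value: (100.0 * counts[arm][o.value] / total if total else 0.0)
            for o in OUTCOMES
        }

    trajectory = trajectory_statistics(records)

    tests: list[dict] = []
    if run_tests:
        tests = _run_enrichment_tests(counts, per_state, trajectory)

    return EvaluationReport(records, counts, percentages, per_state, trajectory, tests)


def trajectory_statistics(records: Sequence[TransitionRecord]) -> dict:
    """Per-arm counts of patients with >=90% better / worse transitions.

    A patient enters an arm's denominator only with at least one transition
    in that arm; the 90% threshold is inclusive.  Both strictly-better and
    better-or-same variants are reported.
    """
    per_patient: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        arm = "followed" if r.followed else "not_followed"
        bucket = per_patient.setdefault(
            (r.patient_id, arm), {o.value: 0 for o in OUTCOMES}
        )
        bucket[r.outcome.value] += 1

    out = {}
    for arm in ARMS:
        n_patients = 0
        ge90_better = 0
        ge90_better_same = 0
        ge90_worse = 0
        for (pid, a), c in per_patient.items():
            if a != arm:
                continue
            total = sum(c.values())
            if total == 0:
                continue
            n_patients += 1
            if c["better"] / total >= 0.9:
                ge90_better += 1
            if (c["better"] + c["same"]) / total >= 0.9:
                ge90_better_same += 1
            if c["worse"] / total >= 0.9:
                ge90_worse += 1
        out[arm] = {
            "n_patients": n_patients,
            "ge90_better": ge90_better,
            "ge90_better_or_same": ge90_better_same,
            "ge90_worse": ge90_worse,
        }
    return out


def kfold_split(
    patient_ids: Sequence, k: int = 5, seed: int = 42
) -> list[tuple[list, list]]:
    """Patient-level k-fold partition with a seeded shuffle.

    Returns (train, test) id lists per fold; test folds are disjoint, cover
    all patients, and are sized within one of each other.
    """
    ids = list(patient_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    out = []
    for f in folds:
        test = [ids[i] for i in f]
        test_set = set(f.tolist())
        train = [ids[i] for i in range(len(ids)) if i not in test_set]
        out.append((train, test))
    return out


def enrichment_test(table: Sequence[Sequence[int]]) -> float:
    """One-sided hypergeometric tail for a 2x2 followed x better table.

    ``table = [[followed_better, followed_not], [other_better, other_not]]``.
    Returns P(X >= followed_better) for X hypergeometric with the table's
    margins.  Zero-margin tables return 1.0 by convention.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + c  # total better
    n = a + b  # followed-arm size
    if N == 0 or K == 0 or n == 0:
        return 1.0  # zero-margin convention
    p = float(stats.hypergeom.sf(a - 1, N, K, n))
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return np.clip(adjusted, 0.0, 1.0).tolist()


def _run_enrichment_tests(counts, per_state, trajectory) -> list[dict]:
    tests = []

    def table_from(c_f, c_n, positive_keys):
        a = sum(c_f[k] for k in positive_keys)
        b = sum(v for k, v in c_f.items() if k not in positive_keys)
        c = sum(c_n[k] for k in positive_keys)
        d = sum(v for k, v in c_n.items() if k not in positive_keys)
        return [[a, b], [c, d]]

    c_f, c_n = counts["followed"], counts["not_followed"]
    tests.append({"name": "transitions_better", "table": table_from(c_f, c_n, ("better",))})
    tests.append(
        {
            "name": "transitions_better_or_same",
            "table": table_from(c_f, c_n, ("better", "same")),
        }
    )

    t_f, t_n = trajectory["followed"], trajectory["not_followed"]
    tests.append(
        {
            "name": "trajectories_ge90_better",
            "table": [
                [t_f["ge90_better"], t_f["n_patients"] - t_f["ge90_better"]],
                [t_n["ge90_better"], t_n["n_patients"] - t_n["ge90_better"]],
            ],
        }
    )

    for state in TREATABLE_STATES:
        key_f, key_n = (state.name, "followed"), (state.name, "not_followed")
        if key_f in per_state and key_n in per_state:
            tests.append(
                {
                    "name": f"state_{state.name}_better",
                    "table": table_from(per_state[key_f], per_state[key_n], ("better",)),
                }
            )

    raw = [enrichment_test(t["table"]) for t in tests]
    adj = bh_adjust(raw)
    for t, pr, pa in zip(tests, raw, adj):
        t["p_raw"] = pr
        t["p_adj"] = pa
    return tests


def per_state_policy_table(
    policy: AlphaVectorPolicy, model: PomdpModel
) -> dict[StateLabel, AntibioticAction]:
    """Recommended action at a point-mass belief for each non-absorbing state."""
    out: dict[StateLabel, AntibioticAction] = {}
    for state in StateLabel:
        if state in ABSORBING_STATES:
            continue
        b = np.zeros(model.n_states)
        b[int(state)] = 1.0
        action, _, _ = extract_action(policy, b)
        out[state] = action_from_index(action)
    return out
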