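"""Clinical state space, labeling rules, action encoding, and observation codes.

The model distinguishes ten patient states: eight live states derived from
SIRS criteria, blood-culture evidence of infection and hypotension, plus two
absorbing terminal states (death, dismissal).  Three "probable" states
(PS, BPS, PSS) capture snapshots where missing vitals prevent the SIRS
determination.

Actions are antibiotic combinations: every non-empty subset of the five most
frequent antibiotics plus one catch-all for any other antibiotic (32 actions
total).  Observations discretize five vitals into five bins each, crossed
with a binary blood-culture flag (2 * 5**5 = 6250 codes).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Culture",
    "StateLabel",
    "SEVERITY_ORDER",
    "ABSORBING_STATES",
    "TREATABLE_STATES",
    "Comparison",
    "VitalsSnapshot",
    "OBSERVATION_VITALS",
    "SIRS_VITALS",
    "NAMED_DRUGS",
    "N_ACTIONS",
    "N_OBSERVATIONS",
    "N_VITAL_BINS",
    "AntibioticAction",
    "ObservationCode",
    "NoActionError",
    "count_sirs_criteria",
    "is_hypotensive",
    "sirs_determinable",
    "label_state",
    "compare_states",
    "severity_rank",
    "encode_action",
    "action_from_index",
    "all_actions",
    "observation_index",
    "observation_from_index",
    "codebooks",
]


class Culture(str, enum.Enum):
    """Tri-state blood-culture result."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


class StateLabel(enum.IntEnum):
    """The ten patient states. Integer values index model arrays."""

    NO_SIRS = 0
    SIRS = 1
    SEPSIS = 2
    SEPTIC_SHOCK = 3
    PS = 4  # probable SIRS: no infection, SIRS not determinable
    BACTEREMIA = 5
    BPS = 6  # bacteremia, probable sepsis
    PSS = 7  # probable septic shock
    DEATH = 8
    DISMISSAL = 9


#: Best to worst, consistent with the reward ranking.
SEVERITY_ORDER: tuple[StateLabel, ...] = (
    StateLabel.DISMISSAL,
    StateLabel.NO_SIRS,
    StateLabel.PS,
    StateLabel.SIRS,
    StateLabel.BACTEREMIA,
    StateLabel.BPS,
    StateLabel.PSS,
    StateLabel.SEPSIS,
    StateLabel.SEPTIC_SHOCK,
    StateLabel.DEATH,
)

ABSORBING_STATES: tuple[StateLabel, ...] = (StateLabel.DEATH, StateLabel.DISMISSAL)

#: Live states in which a treatment decision is made.
TREATABLE_STATES: tuple[StateLabel, ...] = tuple(
    s for s in StateLabel if s not in ABSORBING_STATES
)

_SEVERITY_RANK = {s: i for i, s in enumerate(SEVERITY_ORDER)}


class Comparison(str, enum.Enum):
    BETTER = "better"
    SAME = "same"
    WORSE = "worse"


def severity_rank(state: StateLabel) -> int:
    """Position of ``state`` in the best-to-worst severity order (0 = best)."""
    return _SEVERITY_RANK[state]


def compare_states(s1: StateLabel, s2: StateLabel) -> Comparison:
    """Classify the move ``s1 -> s2`` against the severity order."""
    r1, r2 = _SEVERITY_RANK[s1], _SEVERITY_RANK[s2]
    if r2 < r1:
        return Comparison.BETTER
    if r2 > r1:
        return Comparison.WORSE
    return Comparison.SAME


# --------------------------------------------------------------------------
# Vitals snapshots and clinical predicates
# --------------------------------------------------------------------------

#: Vitals entering the observation code, in index order (5**k weights).
OBSERVATION_VITALS: tuple[str, ...] = (
    "temperature",
    "respiratory_rate",
    "wbc",
    "map",
    "sbp",
)

#: Vitals entering the SIRS criteria.
SIRS_VITALS: tuple[str, ...] = ("heart_rate", "respiratory_rate", "temperature", "wbc")


@dataclass(frozen=True)
class VitalsSnapshot:
    """One timestamped set of measurements for a patient.

    Numeric fields are optional; a ``None`` means the measurement is missing
    from the record.  Present values must be finite and strictly positive.
    """

    timestamp: float = 0.0
    temperature: Optional[float] = None  # degrees Celsius
    heart_rate: Optional[float] = None  # beats per minute
    respiratory_rate: Optional[float] = None  # breaths per minute
    wbc: Optional[float] = None  # cells per mm^3
    map: Optional[float] = None  # mm Hg
    sbp: Optional[float] = None  # mm Hg
    blood_culture: Culture = Culture.MISSING

    def __post_init__(self) -> None:
        if not (self.timestamp >= 0 and math.isfinite(self.timestamp)):
            raise ValueError(f"timestamp must be finite and >= 0, got {self.timestamp}")
        for name in ("temperature", "heart_rate", "respiratory_rate", "wbc", "map", "sbp"):
            value = getattr(self, name)
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if not isinstance(self.blood_culture, Culture):
            object.__setattr__(self, "blood_culture", Culture(self.blood_culture))


def count_sirs_criteria(v: VitalsSnapshot) -> tuple[int, int]:
    """Count satisfied SIRS criteria and how many were evaluable.

    Criteria (all strict comparisons): HR > 90, RR > 20, temperature > 38 or
    < 36, WBC > 12000 or < 4000.  Missing fields reduce the evaluable count.
    """
    met = 0
    evaluable = 0
    if v.heart_rate is not None:
        evaluable += 1
        met += v.heart_rate > 90
    if v.respiratory_rate is not None:
        evaluable += 1
        met += v.respiratory_rate > 20
    if v.temperature is not None:
        evaluable += 1
        met += (v.temperature > 38) or (v.temperature < 36)
    if v.wbc is not None:
        evaluable += 1
        met += (v.wbc > 12000) or (v.wbc < 4000)
    return met, evaluable


def is_hypotensive(v: VitalsSnapshot) -> Optional[bool]:
    """SBP < 90 or MAP < 70 on present fields; ``None`` if both are missing."""
    if v.sbp is None and v.map is None:
        return None
    hypo = False
    if v.sbp is not None and v.sbp < 90:
        hypo = True
    if v.map is not None and v.map < 70:
        hypo = True
    return hypo


def sirs_determinable(v: VitalsSnapshot) -> bool:
    """Whether SIRS status can be decided from the present vitals.

    Decidable when at least two criteria are evaluable, or when at least two
    are already met (two met criteria suffice regardless of missing fields).
    """
    met, evaluable = count_sirs_criteria(v)
    return evaluable >= 2 or met >= 2


def label_state(
    v: VitalsSnapshot,
    outcome_event: Optional[str] = None,
) -> StateLabel:
    """Assign the unique clinical state for a snapshot.

    ``outcome_event`` in {"death", "dismissal"} short-circuits to the
    corresponding absorbing state.  Otherwise rules fire most-severe-first so
    that exactly one applies:

    septic shock > sepsis > PSS > BPS > bacteremia > SIRS > PS > no-SIRS.
    """
    if outcome_event is not None and outcome_event != "none":
        if outcome_event == "death":
            return StateLabel.DEATH
        if outcome_event == "dismissal":
            return StateLabel.DISMISSAL
        raise ValueError(f"unknown outcome event: {outcome_event!r}")

    met, evaluable = count_sirs_criteria(v)
    determinable = evaluable >= 2 or met >= 2
    sirs = met >= 2
    infection = v.blood_culture is Culture.POSITIVE
    hypo = is_hypotensive(v)

    if infection and sirs and hypo is True:
        return StateLabel.SEPTIC_SHOCK
    if infection and sirs:
        return StateLabel.SEPSIS
    if infection and not determinable and hypo is True:
        return StateLabel.PSS
    if infection and not determinable:
        return StateLabel.BPS
    if infection:
        # determinable and fewer than 2 criteria met
        return StateLabel.BACTEREMIA
    if sirs:
        return StateLabel.SIRS
    if not determinable:
        return StateLabel.PS
    return StateLabel.NO_SIRS


# --------------------------------------------------------------------------
# Antibiotic actions
# --------------------------------------------------------------------------

#: The five most frequently used antibiotics, in bit order.
NAMED_DRUGS: tuple[str, ...] = (
    "VANCOMYCIN",
    "CEFEPIME",
    "METRONIDAZOLE",
    "CEFTRIAXONE",
    "MEROPENEM",
)

N_ACTIONS = 32
#: Index of the catch-all "other antibiotics" action.
OTHER_ACTION_INDEX = N_ACTIONS - 1


class NoActionError(ValueError):
    """Raised when an empty drug set is encoded (distinct from catch-all)."""


@dataclass(frozen=True)
class AntibioticAction:
    """One of the 32 treatment actions.

    Indices 0..30 are the non-empty subsets of :data:`NAMED_DRUGS` (ordered
    by bitmask); index 31 is the catch-all for unlisted antibiotics.
    """

    drug_set: frozenset[str]
    other_flag: bool
    index: int

    def __post_init__(self) -> None:
        if not (0 <= self.index < N_ACTIONS):
            raise ValueError(f"action index out of range: {self.index}")
        if self.other_flag and self.drug_set:
            raise ValueError("catch-all action carries no named drugs")
        if not self.other_flag and not self.drug_set:
            raise ValueError("non-catch-all action needs at least one drug")

    def __str__(self) -> str:
        if self.other_flag:
            return "OTHER"
        return ",".join(sorted(self.drug_set))


def _mask_of(drugs: Iterable[str]) -> int:
    mask = 0
    for i, name in enumerate(NAMED_DRUGS):
        if name in drugs:
            mask |= 1 << i
    return mask


def action_from_index(index: int) -> AntibioticAction:
    """Decode an action index back to its drug subset / catch-all."""
    if index == OTHER_ACTION_INDEX:
        return AntibioticAction(frozenset(), True, index)
    mask = index + 1  # indices 0..30 <-> masks 1..31
    if not (1 <= mask <= 31):
        raise ValueError(f"action index out of range: {index}")
    drugs = frozenset(NAMED_DRUGS[i] for i in range(5) if mask & (1 << i))
    return AntibioticAction(drugs, False, index)


def encode_action(drugs: Iterable[str]) -> AntibioticAction:
    """Map an administered drug set to its action.

    The intersection with the five named antibiotics selects the subset
    action; if no named drug was given but something else was, the catch-all
    action fires.  An empty input raises :class:`NoActionError`.
    """
    drug_set = {d for d in drugs}
    if not drug_set:
        raise NoActionError("no antibiotics administered")
    if any(not isinstance(d, str) or not d for d in drug_set):
        raise ValueError("drug names must be non-empty strings")
    mask = _mask_of(drug_set)
    if mask == 0:
        return AntibioticAction(frozenset(), True, OTHER_ACTION_INDEX)
    named = frozenset(NAMED_DRUGS[i] for i in range(5) if mask & (1 << i))
    return AntibioticAction(named, False, mask - 1)


def all_actions() -> list[AntibioticAction]:
    """The complete 32-action set, in index order."""
    return [action_from_index(i) for i in range(N_ACTIONS)]


# --------------------------------------------------------------------------
# Observation codes
# --------------------------------------------------------------------------

N_VITAL_BINS = 5
N_OBSERVATIONS = 2 * N_VITAL_BINS ** len(OBSERVATION_VITALS)  # 6250


@dataclass(frozen=True)
class ObservationCode:
    """A discretized observation: five vital bins plus a blood-culture flag."""

    vital_bins: tuple[int, int, int, int, int]
    blood_flag: int
    index: int
    imputed: frozenset[str] = field(default_factory=frozenset)  # vitals missing at encode time

    def __post_init__(self) -> None:
        if len(self.vital_bins) != 5 or any(
            not (0 <= b < N_VITAL_BINS) for b in self.vital_bins
        ):
            raise ValueError(f"invalid vital bins: {self.vital_bins}")
        if self.blood_flag not in (0, 1):
            raise ValueError(f"blood flag must be 0/1, got {self.blood_flag}")
        expected = observation_index(self.vital_bins, self.blood_flag)
        if self.index != expected:
            raise ValueError(f"index {self.index} inconsistent with fields ({expected})")


def observation_index(vital_bins: Sequence[int], blood_flag: int) -> int:
    """index = blood_flag * 5**5 + sum_k bins[k] * 5**k."""
    idx = blood_flag * N_VITAL_BINS ** 5
    for k, b in enumerate(vital_bins):
        idx += b * N_VITAL_BINS ** k
    return idx


def observation_from_index(index: int) -> ObservationCode:
    if not (0 <= index < N_OBSERVATIONS):
        raise ValueError(f"observation index out of range: {index}")
    blood_flag, rest = divmod(index, N_VITAL_BINS ** 5)
    bins = []
    for _ in range(5):
        bins.append(rest % N_VITAL_BINS)
        rest //= N_VITAL_BINS
    return ObservationCode(tuple(bins), blood_flag, index)


def codebooks() -> dict:
    """JSON-serializable code books for states, actions and observations."""
    return {
        "states": {s.name: int(s.value) for s in StateLabel},
        "severity_order": [s.name for s in SEVERITY_ORDER],
        "actions": {
            str(a.index): {"drugs": sorted(a.drug_set), "other": a.other_flag}
            for a in all_actions()
        },
        "observation": {
            "vitals": list(OBSERVATION_VITALS),
            "bins_per_vital": N_VITAL_BINS,
            "n_codes": N_OBSERVATIONS,
            "index_formula": "blood_flag*5^5 + sum_k bin_k*5^k",
        },
    }


def write_codebooks(path) -> None:
    with open(path, "w") as fh:
        json.dump(codebooks(), fh, indent=2)
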