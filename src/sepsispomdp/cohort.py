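"""Reading and writing patient trajectory tables.

The cohort file is a plain CSV with one row per timestamped record:

    patient_id, timestamp, temperature, heart_rate, respiratory_rate,
    wbc, map, sbp, blood_culture {pos,neg,NA}, antibiotics
    (semicolon-joined names), outcome {none,death,dismissal}

Missing numeric values are empty cells.  A terminal death/dismissal event is
a row whose ``outcome`` column is set; vitals on that row may be empty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .states import Culture, StateLabel, VitalsSnapshot, label_state

__all__ = ["TimePoint", "Patient", "read_cohort", "write_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = (
    "patient_id",
    "timestamp",
    "temperature",
    "heart_rate",
    "respiratory_rate",
    "wbc",
    "map",
    "sbp",
    "blood_culture",
    "antibiotics",
    "outcome",
)

_CULTURE_TO_CSV = {Culture.POSITIVE: "pos", Culture.NEGATIVE: "neg", Culture.MISSING: "NA"}
_CULTURE_FROM_CSV = {v: k for k, v in _CULTURE_TO_CSV.items()}


@dataclass
class TimePoint:
    """One row of a patient trajectory."""

    vitals: VitalsSnapshot
    antibiotics: frozenset[str] = field(default_factory=frozenset)
    outcome: Optional[str] = None  # None, "death" or "dismissal"

    def label(self) -> StateLabel:
        return label_state(self.vitals, self.outcome)


@dataclass
class Patient:
    """A patient's full timestamped trajectory, ordered by timestamp."""

    patient_id: str
    timepoints: list[TimePoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timepoints.sort(key=lambda tp: tp.vitals.timestamp)

    def labels(self) -> list[StateLabel]:
        return [tp.label() for tp in self.timepoints]

    @property
    def outcome(self) -> Optional[str]:
        for tp in self.timepoints:
            if tp.outcome is not None:
                return tp.outcome
        return None


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def _parse(cell: str) -> Optional[float]:
    cell = cell.strip()
    return None if cell == "" else float(cell)


def write_cohort(patients: Iterable[Patient], path) -> None:
    """Write patients to the cohort CSV layout (lossless float round trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for patient in patients:
            for tp in patient.timepoints:
                v = tp.vitals
                writer.writerow(
                    [
                        patient.patient_id,
                        repr(v.timestamp),
                        _fmt(v.temperature),
                        _fmt(v.heart_rate),
                        _fmt(v.respiratory_rate),
                        _fmt(v.wbc),
                        _fmt(v.map),
                        _fmt(v.sbp),
                        _CULTURE_TO_CSV[v.blood_culture],
                        ";".join(sorted(tp.antibiotics)),
                        tp.outcome or "none",
                    ]
                )


def read_cohort(path) -> list[Patient]:
    """Read a cohort CSV into :class:`Patient` objects, ordered by timestamp."""
    by_id: dict[str, list[TimePoint]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"cohort file missing columns: {sorted(missing)}")
        for row in reader:
            pid = row["patient_id"]
            if pid not in by_id:
                by_id[pid] = []
                order.append(pid)
            vitals = VitalsSnapshot(
                timestamp=float(row["timestamp"]),
                temperature=_parse(row["temperature"]),
                heart_rate=_parse(row["heart_rate"]),
                respiratory_rate=_parse(row["respiratory_rate"]),
                wbc=_parse(row["wbc"]),
                map=_parse(row["map"]),
                sbp=_parse(row["sbp"]),
                blood_culture=_CULTURE_FROM_CSV[row["blood_culture"].strip()],
            )
            drugs = frozenset(d for d in row["antibiotics"].split(";") if d)
            outcome = row["outcome"].strip()
            by_id[pid].append(
                TimePoint(vitals, drugs, None if outcome in ("", "none") else outcome)
            )
    return [Patient(pid, by_id[pid]) for pid in order]
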