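"""Domain types, file I/O, and participant screening rules.

The study population is split into three age strata commonly used in
gerontology: young adults (18-22 years), young-old adults (65-74 years) and
old-old adults (>= 75 years).  Each kept participant contributes one
in-phase and one anti-phase bimanual tapping trial, recorded as two
thumb-index distance waveforms (left and right hand, millimetres) sampled at
a fixed rate for a fixed duration (15 s by default).

Screening removes, in a fixed and therefore reproducible order:
pre-screened musculoskeletal / CNS / mental disorders, left-handed
participants, trials whose aperture ever reaches 300 mm (sensor artefact),
participants with incomplete recordings, ages outside every stratum, and --
for the older strata only -- suspected cognitive impairment (MMSE <= 23).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "Hand",
    "Group",
    "Participant",
    "TappingTrial",
    "Cohort",
    "TrialFormatError",
    "AGE_RANGES",
    "MAX_AMPLITUDE_MM",
    "MMSE_CUTOFF",
    "assign_age_group",
    "max_amplitude",
    "apply_exclusions",
    "read_trial",
    "write_trial",
    "read_cohort_metadata",
    "write_cohort_metadata",
]


class Task(str, enum.Enum):
    """Bimanual tapping condition."""

    IN_PHASE = "in_phase"
    ANTI_PHASE = "anti_phase"


class Hand(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Group(str, enum.Enum):
    """Age stratum: young, young-old and old-old adults."""

    YA = "YA"
    YOA = "YOA"
    OOA = "OOA"


#: Inclusive age ranges per stratum; ``None`` means unbounded above.
AGE_RANGES: dict[Group, tuple[int, Optional[int]]] = {
    Group.YA: (18, 22),
    Group.YOA: (65, 74),
    Group.OOA: (75, None),
}

#: Trials whose aperture reaches this value anywhere are sensor artefacts.
MAX_AMPLITUDE_MM = 300.0

#: MMSE at or below this value flags suspected cognitive impairment.
MMSE_CUTOFF = 23


class TrialFormatError(ValueError):
    """Raised when a trial file violates the on-disk format contract."""


@dataclass(frozen=True)
class Participant:
    """One study participant.

    ``mmse`` may be absent only for young adults (the cognitive screen is
    applied to the older strata).  ``prescreened_disorder`` carries the
    pre-screening outcome for musculoskeletal / CNS / mental disorders; the
    analysis cannot diagnose these, so they arrive as a boolean flag.
    """

    id: str
    age: int
    sex: str
    handedness: str
    mmse: Optional[int] = None
    group: Optional[Group] = None
    prescreened_disorder: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.age, (int, np.integer)) or isinstance(self.age, bool):
            raise ValueError(f"age must be an integer, got {self.age!r}")
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"mmse must be within 0-30, got {self.mmse}")


@dataclass(frozen=True)
class TappingTrial:
    """One participant x task recording: two distance channels in mm."""

    participant_id: str
    task: Task
    sampling_rate: float
    duration: float
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        object.__setattr__(self, "task", Task(self.task))
        expected = round(self.sampling_rate * self.duration) + 1
        if left.ndim != 1 or right.ndim != 1:
            raise TrialFormatError("channels must be one-dimensional")
        if len(left) != len(right):
            raise TrialFormatError(
                f"channel lengths differ: left={len(left)} right={len(right)}"
            )
        if len(left) != expected:
            raise TrialFormatError(
                f"channel length {len(left)} does not match "
                f"round(rate*duration)+1 = {expected}"
            )
        if np.isnan(left).any() or np.isnan(right).any():
            raise TrialFormatError("channels contain missing values")
        if (left < 0).any() or (right < 0).any():
            raise TrialFormatError("distances must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, hand: Hand) -> np.ndarray:
        return self.left if Hand(hand) is Hand.LEFT else self.right


@dataclass
class Cohort:
    """Participants plus their trials and the log of screening exclusions."""

    participants: list[Participant] = field(default_factory=list)
    trials: list[TappingTrial] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def trials_of(self, participant_id: str) -> list[TappingTrial]:
        return [t for t in self.trials if t.participant_id == participant_id]


def assign_age_group(age: int) -> Optional[Group]:
    """Map an integer age to its stratum, or ``None`` if no stratum covers it.

    Ages between the recruited ranges (23-64) are not covered by any stratum
    and lead to exclusion with reason ``"age_out_of_range"`` during screening.
    """
    if isinstance(age, bool) or not isinstance(age, (int, np.integer)):
        raise ValueError(f"age must be an integer, got {age!r}")
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    for group, (lo, hi) in AGE_RANGES.items():
        if age >= lo and (hi is None or age <= hi):
            return group
    return None


def max_amplitude(trial: TappingTrial) -> float:
    """Maximum aperture over both channels of a trial, in mm."""
    if trial.n_samples == 0:
        raise ValueError("trial has empty channels")
    return float(max(trial.left.max(), trial.right.max()))


def _exclusion_reason(p: Participant, trials: list[TappingTrial]) -> Optional[str]:
    """First matching exclusion reason for a participant, or None if kept."""
    if p.prescreened_disorder:
        return "prescreened_disorder"
    if p.handedness == "left":
        return "left_handed"
    if any(max_amplitude(t) >= MAX_AMPLITUDE_MM for t in trials):
        return "amplitude_ge_300"
    tasks = sorted(t.task.value for t in trials)
    if tasks != [Task.ANTI_PHASE.value, Task.IN_PHASE.value]:
        return "incomplete_trials"
    group = assign_age_group(p.age)
    if group is None:
        return "age_out_of_range"
    if group in (Group.YOA, Group.OOA):
        if p.mmse is None:
            raise ValueError(
                f"participant {p.id} in group {group.value} is missing an MMSE score"
            )
        if p.mmse <= MMSE_CUTOFF:
            return "mmse_le_23"
    return None


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, list[tuple[str, str]]]:
    """Screen a cohort, returning the kept cohort and the exclusion log.

    Criteria are applied per participant in a fixed order (pre-screened
    disorder, left-handedness, >= 300 mm aperture, incomplete trials, age
    outside every stratum, MMSE <= 23 for the older strata) and only the
    first matching reason is logged, so the log is deterministic.  Kept
    participants receive their age-group label.  The operation is
    idempotent.
    """
    kept_participants: list[Participant] = []
    kept_trials: list[TappingTrial] = []
    log: list[tuple[str, str]] = []
    seen: set[str] = set()
    for p in cohort.participants:
        if p.id in seen:
            raise ValueError(f"duplicate participant id {p.id!r}")
        seen.add(p.id)
        trials = cohort.trials_of(p.id)
        reason = _exclusion_reason(p, trials)
        if reason is not None:
            log.append((p.id, reason))
            continue
        kept_participants.append(replace(p, group=assign_age_group(p.age)))
        kept_trials.extend(trials)
    full_log = list(cohort.exclusion_log) + log
    return Cohort(kept_participants, kept_trials, full_log), full_log


# ---------------------------------------------------------------------------
# Trial and metadata I/O
#
# A trial is a plain-text CSV (`time_s,left_mm,right_mm`, one row per sample)
# with a JSON sidecar holding the metadata; cohort metadata is a CSV with
# header `id,age,sex,handedness,mmse`.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trial(trial: TappingTrial, path: str | Path) -> None:
    """Write a trial as CSV plus JSON sidecar (full float precision)."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trial.time, "left_mm": trial.left, "right_mm": trial.right}
    )
    # %.17g is lossless for doubles, so write/read round-trips bit-exactly.
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "participant_id": trial.participant_id,
        "task": trial.task.value,
        "sampling_rate_hz": trial.sampling_rate,
        "duration_s": trial.duration,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trial(path: str | Path) -> TappingTrial:
    """Read a trial written by :func:`write_trial`, validating the format."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TrialFormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise TrialFormatError(f"invalid JSON sidecar {sidecar}: {exc}") from exc
    required = {"participant_id", "task", "sampling_rate_hz", "duration_s"}
    missing = required - meta.keys()
    if missing:
        raise TrialFormatError(f"sidecar missing keys: {sorted(missing)}")
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "left_mm", "right_mm"]:
        raise TrialFormatError(
            f"expected columns time_s,left_mm,right_mm, got {list(df.columns)}"
        )
    try:
        task = Task(meta["task"])
    except ValueError as exc:
        raise TrialFormatError(f"unknown task {meta['task']!r}") from exc
    try:
        return TappingTrial(
            participant_id=str(meta["participant_id"]),
            task=task,
            sampling_rate=float(meta["sampling_rate_hz"]),
            duration=float(meta["duration_s"]),
            left=df["left_mm"].to_numpy(),
            right=df["right_mm"].to_numpy(),
        )
    except TrialFormatError:
        raise
    except ValueError as exc:
        raise TrialFormatError(str(exc)) from exc


def write_cohort_metadata(participants: Sequence[Participant], path: str | Path) -> None:
    rows = [
        {
            "id": p.id,
            "age": p.age,
            "sex": p.sex,
            "handedness": p.handedness,
            "mmse": "" if p.mmse is None else p.mmse,
        }
        for p in participants
    ]
    pd.DataFrame(rows, columns=["id", "age", "sex", "handedness", "mmse"]).to_csv(
        path, index=False
    )


def read_cohort_metadata(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, dtype={"id": str})
    required = ["id", "age", "sex", "handedness", "mmse"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialFormatError(f"cohort metadata missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        mmse = None if pd.isna(row.mmse) else int(row.mmse)
        out.append(
            Participant(
                id=str(row.id),
                age=int(row.age),
                sex=str(row.sex),
                handedness=str(row.handedness),
                mmse=mmse,
            )
        )
    return out
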