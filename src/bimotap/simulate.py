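"""Synthetic two-channel tapping-trial generator.

The generator targets the statistical structure of magnetic-sensor
thumb-index distance waveforms in a bimanual tapping protocol: 15 s trials,
an in-phase condition (both hands close simultaneously) and an anti-phase
condition (hands alternate, 180 deg target phase), a ~40 mm target aperture,
and group/task/hand-specific tap rates, amplitudes, within-trial
variability, linear fatigue drift of the peak aperture, and inter-hand
phase jitter.

Model, per trial:

* Right-hand contact times form a renewal process: the first contact is at
  t = 0 and successive gaps are i.i.d. truncated normal (lower bound
  0.05 s) with the cell's interval mean/SD.
* Left-hand contact k is the right-hand contact k plus a normal offset whose
  mean is 0 (in-phase) or half the local right-hand cycle (anti-phase) and
  whose SD is ``phase_sd/360`` of the local cycle.
* Each open-close cycle is rendered as a raised-cosine arch from 0 mm at
  contact to a peak drawn from ``Normal(amplitude_mean + fatigue_slope *
  (t - duration/2), amplitude_sd)``, floored at 1 mm.  Anchoring the drift
  at mid-trial makes the trial-average peak equal the cell's amplitude mean
  while preserving the drift slope.
* Subjects carry multiplicative ability factors on their interval and
  amplitude means (shared across cells, which induces the within-subject
  correlation a mixed design exploits).
* White measurement noise (SD 0.2 mm) is added and the signal clipped at 0.

Default cell parameters reproduce the group x task x hand structure of the
screening study this package reimplements (tapping-interval means/SDs,
aperture means/SDs, fatigue slopes, and phase-difference SDs per cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .cohort import Cohort, Group, Hand, Participant, Task, TappingTrial

__all__ = [
    "CellProfile",
    "GroupProfiles",
    "CohortSpec",
    "GroupSpec",
    "SubjectEffects",
    "default_profiles",
    "default_cohort_spec",
    "simulate_tap_times",
    "simulate_trial",
    "simulate_cohort",
]

#: Hard floor for inter-tap gaps (physiological refractory interval), s.
MIN_GAP_S = 0.05

#: Measurement noise SD of the distance sensor model, mm.
NOISE_SD_MM = 0.2

#: Floor for rendered peak apertures, mm.
MIN_PEAK_MM = 1.0


@dataclass(frozen=True)
class CellProfile:
    """Generating parameters for one (group, task, hand) cell."""

    interval_mean: float  # s, mean inter-tap gap
    interval_sd: float  # s, within-trial gap SD
    amplitude_mean: float  # mm, mean peak aperture
    amplitude_sd: float  # mm, within-trial peak SD
    fatigue_slope: float  # mm/s, linear drift of the peak aperture

    def __post_init__(self) -> None:
        if self.interval_mean <= 0:
            raise ValueError("interval_mean must be positive")
        if self.interval_sd < 0:
            raise ValueError("interval_sd must be non-negative")
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be positive")
        if self.amplitude_sd < 0:
            raise ValueError("amplitude_sd must be non-negative")


@dataclass(frozen=True)
class GroupProfiles:
    """Full generating profile: per-cell kinematics plus per (group, task)
    inter-hand phase jitter and the between-subject heterogeneity scale."""

    cells: dict[tuple[Group, Task, Hand], CellProfile]
    phase_sd: dict[tuple[Group, Task], float]  # degrees
    between_subject_cv: float = 0.15

    def cell(self, group: Group, task: Task, hand: Hand) -> CellProfile:
        key = (Group(group), Task(task), Hand(hand))
        if key not in self.cells:
            raise KeyError(f"no profile for cell {key}")
        return self.cells[key]

    def phase_sd_deg(self, group: Group, task: Task) -> float:
        key = (Group(group), Task(task))
        if key not in self.phase_sd:
            raise KeyError(f"no phase profile for {key}")
        return self.phase_sd[key]


# Cell parameter table: (task, hand) -> parameter -> (YA, YOA, OOA).
_CELL_TABLE: dict[tuple[Task, Hand], dict[str, tuple[float, float, float]]] = {
    (Task.IN_PHASE, Hand.LEFT): {
        "interval_mean": (0.28, 0.34, 0.38),
        "interval_sd": (0.03, 0.04, 0.04),
        "amplitude_mean": (41.07, 46.81, 48.11),
        "amplitude_sd": (6.95, 6.71, 6.63),
        "fatigue_slope": (-0.14, -0.14, -0.09),
    },
    (Task.IN_PHASE, Hand.RIGHT): {
        "interval_mean": (0.27, 0.34, 0.38),
        "interval_sd": (0.02, 0.03, 0.04),
        "amplitude_mean": (40.25, 47.01, 48.78),
        "amplitude_sd": (5.26, 5.55, 5.70),
        "fatigue_slope": (-0.08, 0.11, 0.03),
    },
    (Task.ANTI_PHASE, Hand.LEFT): {
        "interval_mean": (0.37, 0.51, 0.59),
        "interval_sd": (0.04, 0.08, 0.10),
        "amplitude_mean": (49.50, 60.55, 62.22),
        "amplitude_sd": (7.06, 7.36, 7.90),
        "fatigue_slope": (-0.21, -0.15, -0.15),
    },
    (Task.ANTI_PHASE, Hand.RIGHT): {
        "interval_mean": (0.37, 0.50, 0.59),
        "interval_sd": (0.03, 0.06, 0.08),
        "amplitude_mean": (47.39, 59.90, 63.15),
        "amplitude_sd": (5.45, 6.87, 7.09),
        "fatigue_slope": (-0.11, -0.10, -0.17),
    },
}

# Phase-difference SD (degrees) per task -> (YA, YOA, OOA).
_PHASE_TABLE: dict[Task, tuple[float, float, float]] = {
    Task.IN_PHASE: (29.60, 27.27, 29.03),
    Task.ANTI_PHASE: (25.88, 33.21, 40.57),
}

_GROUP_ORDER = (Group.YA, Group.YOA, Group.OOA)


def default_profiles(between_subject_cv: float = 0.15) -> GroupProfiles:
    """Generating profiles parameterized from the reference cohort's
    group x task x hand summary statistics."""
    cells: dict[tuple[Group, Task, Hand], CellProfile] = {}
    for (task, hand), params in _CELL_TABLE.items():
        for gi, group in enumerate(_GROUP_ORDER):
            cells[(group, task, hand)] = CellProfile(
                **{name: values[gi] for name, values in params.items()}
            )
    phase = {
        (group, task): values[gi]
        for task, values in _PHASE_TABLE.items()
        for gi, group in enumerate(_GROUP_ORDER)
    }
    return GroupProfiles(cells=cells, phase_sd=phase, between_subject_cv=between_subject_cv)


@dataclass(frozen=True)
class GroupSpec:
    """Simulation parameters for one age stratum."""

    size: int
    age_mean: float
    age_sd: float
    age_range: tuple[int, Optional[int]]
    n_male: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= self.n_male <= self.size:
            raise ValueError("n_male must be within [0, size]")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters (sizes, ages, sex counts, seed)."""

    groups: dict[Group, GroupSpec]
    seed: int = 0
    sampling_rate: float = 100.0
    duration: float = 15.0
    mmse_mean: float = 28.0
    mmse_sd: float = 1.5


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The reference cohort composition: 97 young adults (25 male,
    age 20.73 +/- 1.43), 102 young-old (17 male, 70.77 +/- 2.70) and
    222 old-old (52 male, 80.71 +/- 4.38)."""
    return CohortSpec(
        groups={
            Group.YA: GroupSpec(97, 20.73, 1.43, (18, 22), 25),
            Group.YOA: GroupSpec(102, 70.77, 2.70, (65, 74), 17),
            Group.OOA: GroupSpec(222, 80.71, 4.38, (75, None), 52),
        },
        seed=seed,
    )


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject ability multipliers on the cell means (shared across
    tasks and hands)."""

    interval_scale: float = 1.0
    amplitude_scale: float = 1.0


def simulate_tap_times(
    interval_mean: float,
    interval_sd: float,
    duration: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Ordered contact times of one hand over a trial.

    The first contact is at t = 0; successive gaps are drawn independently
    from a normal truncated below at ``MIN_GAP_S`` with the given mean/SD.
    Generation stops at the last contact <= ``duration``.  Identical seeds
    give identical output.
    """
    if interval_mean <= 0:
        raise ValueError("interval_mean must be positive")
    if interval_sd < 0:
        raise ValueError("interval_sd must be non-negative")
    if interval_sd == 0 and interval_mean < MIN_GAP_S:
        raise ValueError(
            f"interval_mean {interval_mean} below the {MIN_GAP_S}s gap floor"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gaps: list[float] = []
    t = 0.0
    while True:
        gap = interval_mean if interval_sd == 0 else _trunc_normal(rng, interval_mean, interval_sd)
        if t + gap > duration:
            break
        t += gap
        gaps.append(gap)
    return np.concatenate([[0.0], np.cumsum(gaps)]) if gaps else np.array([0.0])


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from Normal(mean, sd) truncated below at MIN_GAP_S."""
    for _ in range(1000):
        g = rng.normal(mean, sd)
        if g >= MIN_GAP_S:
            return g
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def _render_channel(
    contacts: np.ndarray,
    cell: CellProfile,
    amplitude_scale: float,
    duration: float,
    sampling_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render raised-cosine arches between consecutive contacts, add
    measurement noise and clip at zero."""
    n = round(sampling_rate * duration) + 1
    t = np.arange(n) / sampling_rate
    x = np.zeros(n)
    amp_mean = cell.amplitude_mean * amplitude_scale
    mids = 0.5 * (contacts[:-1] + contacts[1:])
    peaks = rng.normal(
        amp_mean + cell.fatigue_slope * (mids - duration / 2.0), cell.amplitude_sd
    )
    peaks = np.maximum(peaks, MIN_PEAK_MM)
    starts = np.searchsorted(t, contacts[:-1], side="left")
    stops = np.searchsorted(t, contacts[1:], side="left")
    for t0, t1, peak, i0, i1 in zip(contacts[:-1], contacts[1:], peaks, starts, stops):
        if i1 > i0:
            x[i0:i1] = 0.5 * peak * (
                1.0 - np.cos(2.0 * np.pi * (t[i0:i1] - t0) / (t1 - t0))
            )
    x += rng.normal(0.0, NOISE_SD_MM, n)
    return np.clip(x, 0.0, None)


def simulate_trial(
    profiles: GroupProfiles,
    participant: Participant,
    task: Task,
    rng: np.random.Generator | int,
    *,
    sampling_rate: float = 100.0,
    duration: float = 15.0,
    effects: SubjectEffects | None = None,
) -> TappingTrial:
    """Simulate one two-channel trial for a participant with a group.

    The right hand is the timing reference; left contacts are phase-coupled
    to it (offset 0 deg in-phase, 180 deg anti-phase, jitter ``phase_sd``).
    Left-hand amplitudes come from the left-hand cell profile; left-hand
    timing statistics are emergent from the right-hand process plus the
    phase jitter.
    """
    if participant.group is None:
        raise ValueError(f"participant {participant.id} has no group")
    task = Task(task)
    group = Group(participant.group)
    cell_r = profiles.cell(group, task, Hand.RIGHT)
    cell_l = profiles.cell(group, task, Hand.LEFT)
    phase_sd = profiles.phase_sd_deg(group, task)
    if effects is None:
        effects = SubjectEffects()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    right = simulate_tap_times(
        cell_r.interval_mean * effects.interval_scale,
        cell_r.interval_sd,
        duration,
        rng,
    )
    if len(right) < 3:
        raise ValueError("trial too short to contain tapping cycles")
    # Local cycle of contact k: gap to the next contact (last contact reuses
    # the preceding gap).
    cycles = np.diff(right)
    local = np.concatenate([cycles, [cycles[-1]]])
    target = np.zeros_like(local) if task is Task.IN_PHASE else local / 2.0
    sigma = phase_sd / 360.0 * local
    left = np.sort(right + rng.normal(target, sigma))
    # Enforce strictly increasing contacts with a minimal separation.
    keep = np.concatenate([[True], np.diff(left) > 1e-3])
    left = left[keep]

    right_x = _render_channel(
        right, cell_r, effects.amplitude_scale, duration, sampling_rate, rng
    )
    left_x = _render_channel(
        left, cell_l, effects.amplitude_scale, duration, sampling_rate, rng
    )
    return TappingTrial(
        participant_id=participant.id,
        task=task,
        sampling_rate=sampling_rate,
        duration=duration,
        left=left_x,
        right=right_x,
    )


def _draw_age(rng: np.random.Generator, spec: GroupSpec) -> int:
    lo, hi = spec.age_range
    for _ in range(1000):
        age = int(round(rng.normal(spec.age_mean, spec.age_sd)))
        if age >= lo and (hi is None or age <= hi):
            return age
    raise RuntimeError("age resampling failed to land in the group range")


def simulate_cohort(
    spec: CohortSpec | None = None,
    profiles: GroupProfiles | None = None,
    seed: int | None = None,
) -> Cohort:
    """Simulate a full cohort: participants with ages, sexes and MMSE in the
    configured counts, plus one in-phase and one anti-phase trial each.

    Fully reproducible: the cohort is a pure function of the spec (and the
    optional ``seed`` override).
    """
    if spec is None:
        spec = default_cohort_spec()
    if profiles is None:
        profiles = default_profiles()
    if seed is not None:
        spec = replace(spec, seed=seed)
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])

    participants: list[Participant] = []
    trials: list[TappingTrial] = []
    for group in _GROUP_ORDER:
        if group not in spec.groups:
            continue
        gspec = spec.groups[group]
        for i in range(gspec.size):
            pid = f"{group.value}{i + 1:03d}"
            age = _draw_age(meta_rng, gspec)
            sex = "male" if i < gspec.n_male else "female"
            if group is Group.YA:
                mmse = None
            else:
                mmse = int(np.clip(round(meta_rng.normal(spec.mmse_mean, spec.mmse_sd)), 24, 30))
            participants.append(
                Participant(
                    id=pid,
                    age=age,
                    sex=sex,
                    handedness="right",
                    mmse=mmse,
                    group=group,
                )
            )
    cv = profiles.between_subject_cv
    subject_seeds = root.spawn(len(participants) + 1)[1:]
    for p, pseed in zip(participants, subject_seeds):
        prng = np.random.default_rng(pseed)
        effects = SubjectEffects(
            interval_scale=float(np.clip(prng.normal(1.0, cv), 0.5, 1.5)),
            amplitude_scale=float(np.clip(prng.normal(1.0, cv), 0.5, 1.5)),
        )
        for task in (Task.IN_PHASE, Task.ANTI_PHASE):
            trials.append(
                simulate_trial(
                    profiles,
                    p,
                    task,
                    prng,
                    sampling_rate=spec.sampling_rate,
                    duration=spec.duration,
                    effects=effects,
                )
            )
    return Cohort(participants=participants, trials=trials)
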