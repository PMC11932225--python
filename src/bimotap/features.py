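"""The nine bimanual-coordination parameters from raw distance waveforms.

Per hand: total traveling distance, average / SD / time-slope of the local
maximum aperture, number of taps, average tapping interval, tap frequency
and SD of the inter-tap interval.  Per trial: the SD of the inter-hand
phase difference (one tap cycle mapped to 360 deg).

Tap detection convention: peaks are local maxima with prominence at least
``min_prominence`` (default 4 mm, 10% of the 40 mm target aperture;
plateaus resolve to their first sample); a tap event is the minimum sample
between each consecutive peak pair.  Contact *times* are refined to
sub-sample precision by intersecting straight-line fits to the two flanks
of sqrt(distance) around the minimum (the aperture leaves a contact
quadratically, so its square root is locally V-shaped), a standard
sub-sample event-timing step in kinematics; contact and peak *values* stay
at the raw samples.  Undefined features (too few taps) propagate as NaN
markers, never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from .cohort import Hand, Task, TappingTrial

__all__ = [
    "TapEvent",
    "HandFeatures",
    "TrialFeatures",
    "HAND_PARAMETERS",
    "PARAMETERS",
    "detect_taps",
    "total_traveling_distance",
    "local_max_stats",
    "tap_interval_stats",
    "phase_difference_sd",
    "extract_features",
    "wrap_angle_deg",
]

#: Default peak prominence threshold, mm (10% of the 40 mm target aperture).
DEFAULT_PROMINENCE_MM = 4.0

#: Per-hand parameter identifiers, in reporting order.
HAND_PARAMETERS = (
    "total_traveling_distance",
    "ave_local_max_distance",
    "sd_local_max_distance",
    "slope_local_max",
    "number_of_taps",
    "ave_tapping_interval",
    "frequency_of_taps",
    "sd_inter_tapping_interval",
)

#: All nine parameter identifiers (phase SD is per trial, hand = "both").
PARAMETERS = HAND_PARAMETERS + ("sd_phase_difference",)


@dataclass(frozen=True)
class TapEvent:
    """One thumb-index contact flanked by an opening peak on each side."""

    contact_time: float  # s, sub-sample refined
    contact_value: float  # mm, raw minimum sample
    preceding_peak: tuple[float, float]  # (time s, value mm)
    following_peak: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.preceding_peak[0] < self.contact_time < self.following_peak[0]:
            # The refined time may not cross its flanking peaks.
            raise ValueError("contact time must lie between its flanking peaks")


@dataclass(frozen=True)
class HandFeatures:
    total_traveling_distance: float
    ave_local_max_distance: float
    sd_local_max_distance: float
    slope_local_max: float
    number_of_taps: float
    ave_tapping_interval: float
    frequency_of_taps: float
    sd_inter_tapping_interval: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HAND_PARAMETERS}


@dataclass(frozen=True)
class TrialFeatures:
    participant_id: str
    task: Task
    left: HandFeatures
    right: HandFeatures
    sd_phase_difference: float

    def as_rows(self) -> list[dict[str, object]]:
        """Long-format rows (participant_id, task, hand, parameter, value)."""
        rows: list[dict[str, object]] = []
        for hand, feats in (("left", self.left), ("right", self.right)):
            for name, value in feats.as_dict().items():
                rows.append(
                    {
                        "participant_id": self.participant_id,
                        "task": self.task.value,
                        "hand": hand,
                        "parameter": name,
                        "value": value,
                    }
                )
        rows.append(
            {
                "participant_id": self.participant_id,
                "task": self.task.value,
                "hand": "both",
                "parameter": "sd_phase_difference",
                "value": self.sd_phase_difference,
            }
        )
        return rows


def _line_fit(idx: list[int], y: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, intercept) of y against sample index."""
    n = len(idx)
    tm = sum(idx) / n
    vm = sum(y[i] for i in idx) / n
    sxx = 0.0
    sxy = 0.0
    for i in idx:
        d = i - tm
        sxx += d * d
        sxy += d * (y[i] - vm)
    slope = sxy / sxx
    return slope, vm - slope * tm


def _refine_contact_time(
    y: np.ndarray, i_min: int, lo: int, hi: int, dt: float
) -> float:
    """Sub-sample contact time from a V fit in the square-root domain.

    ``y`` is sqrt(distance).  Near a contact the aperture rises
    quadratically on both sides, so sqrt(distance) is piecewise linear with
    a kink at the contact; fitting a line to each flank (up to 3 samples,
    skipping the minimum itself) and intersecting them recovers the contact
    time without the bias a single parabola picks up when the two flanking
    arches have unequal curvature.  Falls back to the minimum-sample time
    when the fit is degenerate.
    """
    left_idx = [i for i in (i_min - 3, i_min - 2, i_min - 1) if i > lo]
    right_idx = [i for i in (i_min + 1, i_min + 2, i_min + 3) if i < hi]
    if len(left_idx) >= 2 and len(right_idx) >= 2:
        bl, al = _line_fit(left_idx, y)
        br, ar = _line_fit(right_idx, y)
        if bl < -1e-9 and br > 1e-9:
            pos = (ar - al) / (bl - br)
            if abs(pos - i_min) <= 2.0:
                pos = min(max(pos, lo + 0.5), hi - 0.5)
                return pos * dt
    return i_min * dt


def detect_taps(
    channel: np.ndarray,
    sampling_rate: float,
    min_prominence: float = DEFAULT_PROMINENCE_MM,
) -> list[TapEvent]:
    """Detect tap events on one distance channel.

    Returns the time-ordered list of contacts, each the minimum sample
    between a consecutive pair of prominence-filtered peaks.  An
    all-constant series yields zero events.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("channel must be one-dimensional with >= 3 samples")
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    dt = 1.0 / sampling_rate
    _, props = find_peaks(x, prominence=min_prominence, plateau_size=1)
    peaks = props["left_edges"]  # plateaus resolved to their first sample
    sqrt_x = np.sqrt(np.maximum(x, 0.0))
    events: list[TapEvent] = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        interior = x[p0 + 1 : p1]
        if len(interior) == 0:
            continue
        i_min = int(np.argmin(interior)) + p0 + 1  # first minimum sample
        t_contact = _refine_contact_time(sqrt_x, i_min, p0, p1, dt)
        events.append(
            TapEvent(
                contact_time=t_contact,
                contact_value=float(x[i_min]),
                preceding_peak=(p0 * dt, float(x[p0])),
                following_peak=(p1 * dt, float(x[p1])),
            )
        )
    return events


def total_traveling_distance(channel: np.ndarray) -> float:
    """Sum of absolute sample-to-sample aperture changes, mm."""
    x = np.asarray(channel, dtype=float)
    if len(x) < 2:
        raise ValueError("channel must have >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def _distinct_peaks(taps: Sequence[TapEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicated (by time) flanking peaks of a tap list, time-ordered."""
    seen: dict[float, float] = {}
    for tap in taps:
        for t, v in (tap.preceding_peak, tap.following_peak):
            seen[t] = v
    times = np.array(sorted(seen))
    return times, np.array([seen[t] for t in times])


def local_max_stats(taps: Sequence[TapEvent]) -> tuple[float, float, float]:
    """(mean, sample SD, OLS time-slope) of the local maximum apertures.

    The slope is the least-squares regression of peak value on peak time;
    with no fatigue it is 0, and fatigue drives it negative.  Fewer than two
    distinct peaks yield NaN markers.
    """
    times, values = _distinct_peaks(taps)
    if len(values) < 2:
        return (math.nan, math.nan, math.nan)
    ave = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    slope = float(np.polyfit(times, values, 1)[0])
    return ave, sd, slope


def tap_interval_stats(
    taps: Sequence[TapEvent],
) -> tuple[float, float, float, float]:
    """(number of taps, mean interval s, frequency Hz, sample SD of
    intervals s).  Fewer than two events yield NaN markers for the
    interval-derived values."""
    n = len(taps)
    if n < 2:
        return (float(n), math.nan, math.nan, math.nan)
    contacts = np.array([t.contact_time for t in taps])
    intervals = np.diff(contacts)
    ave = float(np.mean(intervals))
    sd = float(np.std(intervals, ddof=1))
    return (float(n), ave, 1.0 / ave, sd)


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to (-180, 180]."""
    wrapped = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return float(wrapped) if np.isscalar(angle) else wrapped


def phase_difference_sd(
    left_taps: Sequence[TapEvent],
    right_taps: Sequence[TapEvent],
    task: Task,
    method: Literal["circular", "linear"] = "circular",
) -> float:
    """SD of the inter-hand phase difference, degrees.

    The right hand is the reference.  For each right contact r_k with local
    cycle c_k, the left contact nearest the task target (r_k in-phase,
    r_k + c_k/2 anti-phase) gives the angle 360 * (t_left - r_k) / c_k,
    whose deviation from the target (0 or 180 deg) is wrapped to
    (-180, 180].  The default summary is the circular standard deviation;
    ``method="linear"`` uses the plain sample SD of the wrapped deviations.
    Cycles without a nearby left contact are skipped; if all are skipped the
    feature is NaN.
    """
    task = Task(task)
    if len(left_taps) < 3 or len(right_taps) < 3:
        return math.nan
    lefts = np.array([t.contact_time for t in left_taps])
    rights = np.array([t.contact_time for t in right_taps])
    target_deg = 0.0 if task is Task.IN_PHASE else 180.0
    deviations = []
    for k in range(len(rights) - 1):
        c = rights[k + 1] - rights[k]
        if c <= 0:
            continue
        target_t = rights[k] + (0.0 if task is Task.IN_PHASE else c / 2.0)
        j = int(np.argmin(np.abs(lefts - target_t)))
        if abs(lefts[j] - target_t) > c:
            continue  # no left contact within this cycle or its neighbours
        angle = 360.0 * (lefts[j] - rights[k]) / c
        deviations.append(wrap_angle_deg(angle - target_deg))
    if not deviations:
        return math.nan
    dev = np.asarray(deviations)
    if method == "linear":
        if len(dev) < 2:
            return math.nan
        return float(np.std(dev, ddof=1))
    rad = np.deg2rad(dev)
    rbar = float(np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad))))
    if rbar <= 1e-12:
        return math.nan
    return float(np.degrees(math.sqrt(-2.0 * math.log(rbar))))


def _hand_features(
    channel: np.ndarray, sampling_rate: float, min_prominence: float
) -> tuple[HandFeatures, list[TapEvent]]:
    taps = detect_taps(channel, sampling_rate, min_prominence)
    n, ave_iti, freq, sd_iti = tap_interval_stats(taps)
    ave_peak, sd_peak, slope = local_max_stats(taps)
    feats = HandFeatures(
        total_traveling_distance=total_traveling_distance(channel),
        ave_local_max_distance=ave_peak,
        sd_local_max_distance=sd_peak,
        slope_local_max=slope,
        number_of_taps=n,
        ave_tapping_interval=ave_iti,
        frequency_of_taps=freq,
        sd_inter_tapping_interval=sd_iti,
    )
    return feats, taps


def extract_features(
    trial: TappingTrial,
    min_prominence: float = DEFAULT_PROMINENCE_MM,
    phase_method: Literal["circular", "linear"] = "circular",
) -> TrialFeatures:
    """All nine parameters of one trial (per-hand plus the phase SD)."""
    left_feats, left_taps = _hand_features(trial.left, trial.sampling_rate, min_prominence)
    right_feats, right_taps = _hand_features(trial.right, trial.sampling_rate, min_prominence)
    phase_sd = phase_difference_sd(left_taps, right_taps, trial.task, phase_method)
    return TrialFeatures(
        participant_id=trial.participant_id,
        task=trial.task,
        left=left_feats,
        right=right_feats,
        sd_phase_difference=phase_sd,
    )
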