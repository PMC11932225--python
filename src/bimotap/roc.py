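"""ROC construction and Youden-index age cutoffs for coordination screening.

Given per-participant tapping parameters and ages, each parameter is first
binarized into a low/high performance state (the screening target), then
age is evaluated as the predictor of low performance: Mann-Whitney AUC,
Hanley-McNeil standard error, normal-approximation 95% CI, and the age
cutoff that maximizes the Youden index (sensitivity + specificity - 1) over
midpoints between adjacent distinct ages.

The low-performance state is not part of the recorded protocol, so it is a
configurable rule: the default is a whole-sample median split in the
parameter's "worse" direction (ties go to the better class); the
alternative ``young_ref_1sd`` rule marks values worse than the young-adult
mean by more than one young-adult SD.  The rule in force is recorded in the
panel output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import parameters_distinguishing_all_groups

__all__ = [
    "HIGHER_IS_BETTER",
    "LOWER_IS_BETTER",
    "ROCResult",
    "binarize_performance",
    "auc_mann_whitney",
    "auc_se_hanley_mcneil",
    "ci95",
    "youden_cutoff",
    "run_roc_panel",
    "round_half_up",
]

#: Parameters where larger values indicate better coordination.
HIGHER_IS_BETTER = frozenset(
    {
        "total_traveling_distance",
        "ave_local_max_distance",
        "number_of_taps",
        "frequency_of_taps",
    }
)

#: Parameters where smaller values indicate better coordination.
LOWER_IS_BETTER = frozenset(
    {
        "sd_local_max_distance",
        "slope_local_max",
        "ave_tapping_interval",
        "sd_inter_tapping_interval",
        "sd_phase_difference",
    }
)


def round_half_up(value: float, digits: int) -> float:
    """Decimal rounding with ties away from zero (as printed tables round)."""
    value = float(value)
    if not np.isfinite(value):
        return value
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def binarize_performance(
    values: Sequence[float],
    parameter: str,
    rule: Literal["median", "young_ref_1sd"] = "median",
    young_values: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Binary low-performance states (1 = low performance) for a parameter.

    ``median``: whole-sample median split in the parameter's worse
    direction, ties assigned to the better class.  ``young_ref_1sd``: worse
    than the young-group mean by more than one young-group SD (requires
    ``young_values``).
    """
    v = np.asarray(values, dtype=float)
    if parameter in HIGHER_IS_BETTER:
        higher_better = True
    elif parameter in LOWER_IS_BETTER:
        higher_better = False
    else:
        raise ValueError(f"unknown performance direction for parameter {parameter!r}")
    if rule == "median":
        med = float(np.median(v))
        states = v < med if higher_better else v > med
    elif rule == "young_ref_1sd":
        if young_values is None:
            raise ValueError("young_ref_1sd rule requires young_values")
        ref = np.asarray(young_values, dtype=float)
        mean, sd = float(ref.mean()), float(ref.std(ddof=1))
        states = v < mean - sd if higher_better else v > mean + sd
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    return states.astype(int)


def _check_states(states: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(states == 1))
    n_neg = int(np.sum(states == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both state classes must be non-empty")
    return n_pos, n_neg


def auc_mann_whitney(predictor: Sequence[float], states: Sequence[int]) -> float:
    """Mann-Whitney AUC: concordant pairs plus half ties over all
    positive x negative pairs (positive = low performance)."""
    x = np.asarray(predictor, dtype=float)
    s = np.asarray(states, dtype=int)
    n_pos, n_neg = _check_states(s)
    ranks = stats.rankdata(x)
    r_pos = ranks[s == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_se_hanley_mcneil(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a nonparametric AUC."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be within [0, 1]")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 observations per class")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def ci95(auc: float, se: float) -> tuple[float, float]:
    """Normal-approximation 95% CI, clipped to [0, 1]."""
    if se < 0:
        raise ValueError("se must be non-negative")
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return lo, hi


def youden_cutoff(
    predictor: Sequence[float], states: Sequence[int]
) -> tuple[float, float, float, float]:
    """(cutoff, sensitivity, specificity, Youden index) maximizing
    Sn + Sp - 1 over midpoints between adjacent distinct predictor values;
    a case is classified positive when predictor >= cutoff.  Ties break
    toward the lower cutoff."""
    x = np.asarray(predictor, dtype=float)
    s = np.asarray(states, dtype=int)
    n_pos, n_neg = _check_states(s)
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("predictor must take at least two distinct values")
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for thr in thresholds:  # ascending, strict improvement keeps lowest tie
        pred_pos = x >= thr
        sn = float(np.sum(pred_pos & (s == 1)) / n_pos)
        sp = float(np.sum(~pred_pos & (s == 0)) / n_neg)
        yi = sn + sp - 1.0
        if best is None or yi > best[3] + 1e-12:
            best = (float(thr), sn, sp, yi)
    return best


@dataclass(frozen=True)
class ROCResult:
    """ROC summary for one (parameter, task, hand) cell."""

    parameter: str
    task: str
    hand: str
    rule: str
    n_pos: int
    n_neg: int
    auc: float
    auc_se: float
    p: float  # two-sided normal test of AUC = 0.5
    ci95: tuple[float, float]
    cutoff: float  # years
    sensitivity: float
    specificity: float
    youden_index: float


def run_roc_panel(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    parameters: Optional[Iterable[str]] = None,
    rule: Literal["median", "young_ref_1sd"] = "median",
    alpha: float = 0.05,
) -> list[ROCResult]:
    """ROC age-cutoff panel over the eligible parameters.

    ``features`` is the long table (participant_id, task, hand, parameter,
    value) and ``meta`` carries participant_id, age and group.  When
    ``parameters`` is None the eligible set is derived from the post-hoc
    rule (all pairwise group differences significant in both tasks);
    explicitly requested but ineligible parameters are skipped with a
    warning.  One result per (parameter, task, hand in {left, right}).
    """
    merged = features.drop(columns=["age", "group"], errors="ignore").merge(
        meta[["participant_id", "age", "group"]], on="participant_id", how="inner"
    )
    eligible = parameters_distinguishing_all_groups(merged, alpha=alpha)
    eligible_hand = [p for p in eligible if p != "sd_phase_difference"]
    if parameters is None:
        use = eligible_hand
    else:
        use = []
        for p in parameters:
            if p in eligible_hand:
                use.append(p)
            else:
                warnings.warn(
                    f"parameter {p!r} does not separate all three groups in both "
                    "tasks; skipped from the ROC panel"
                )
    results: list[ROCResult] = []
    for parameter in use:
        for task in ("in_phase", "anti_phase"):
            for hand in ("left", "right"):
                d = merged[
                    (merged["parameter"] == parameter)
                    & (merged["task"] == task)
                    & (merged["hand"] == hand)
                ].dropna(subset=["value"])
                values = d["value"].to_numpy()
                ages = d["age"].to_numpy(dtype=float)
                young = d.loc[d["group"] == "YA", "value"].to_numpy()
                states = binarize_performance(values, parameter, rule, young_values=young)
                n_pos, n_neg = _check_states(states)
                auc = auc_mann_whitney(ages, states)
                se = auc_se_hanley_mcneil(auc, n_pos, n_neg)
                z = (auc - 0.5) / se if se > 0 else math.inf
                p = 2.0 * stats.norm.sf(abs(z))
                lo, hi = ci95(auc, se)
                cutoff, sn, sp, yi = youden_cutoff(ages, states)
                results.append(
                    ROCResult(
                        parameter=parameter,
                        task=task,
                        hand=hand,
                        rule=rule,
                        n_pos=n_pos,
                        n_neg=n_neg,
                        auc=auc,
                        auc_se=se,
                        p=p,
                        ci95=(lo, hi),
                        cutoff=cutoff,
                        sensitivity=sn,
                        specificity=sp,
                        youden_index=yi,
                    )
                )
    return results


def panel_to_frame(results: Sequence[ROCResult]) -> pd.DataFrame:
    """Tabulate a panel at the reporting precision (AUC/CI/YI 2 dp, SE 3 dp,
    cutoff 0.1 year, sensitivity/specificity in % to 1 dp)."""
    rows = []
    for r in results:
        rows.append(
            {
                "parameter": r.parameter,
                "task": r.task,
                "hand": r.hand,
                "rule": r.rule,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "auc": round_half_up(r.auc, 2),
                "auc_se": round_half_up(r.auc_se, 3),
                "p": round_half_up(r.p, 4),
                "cutoff_years": round_half_up(r.cutoff, 1),
                "ci_lower": round_half_up(r.ci95[0], 2),
                "ci_upper": round_half_up(r.ci95[1], 2),
                "sensitivity_pct": round_half_up(100.0 * r.sensitivity, 1),
                "specificity_pct": round_half_up(100.0 * r.specificity, 1),
                "youden_index": round_half_up(r.youden_index, 2),
            }
        )
    return pd.DataFrame(rows)
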