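"""Group-comparison statistics for the tapping parameters.

Implements the comparative analysis plan of the screening design: a
chi-square test on sex ratios, mixed-design ANOVAs (between factor: age
group; within factors: hand and/or task, each with two levels) with
Bonferroni post-hoc tests, and Pearson correlations between age and every
parameter cell.

The mixed ANOVA uses Type-III sums of squares via the classic univariate
contrast reduction, which is exact when every within factor has two levels:
each within-subject effect collapses to a single contrast score per
subject, whose unweighted-grand-mean test gives the within main effect and
whose one-way group ANOVA gives the interaction with group; the
between-subjects effect is the one-way ANOVA of the subject means.  With
two-level within factors no sphericity correction is needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Group
from .features import HAND_PARAMETERS

__all__ = [
    "chi_square_counts",
    "mixed_anova",
    "two_way_mixed_anova",
    "bonferroni_posthoc",
    "pearson_age_correlations",
    "pairwise_group_tests",
    "parameters_distinguishing_all_groups",
    "GROUP_ORDER",
]

GROUP_ORDER = ("YA", "YOA", "OOA")

_WITHIN_LEVELS = {"hand": ("left", "right"), "task": ("in_phase", "anti_phase")}


def chi_square_counts(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table.

    Returns ``(statistic, df, p)`` with ``df = (r-1)(c-1)``.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mixed-design ANOVA
# ---------------------------------------------------------------------------


def _oneway(y: np.ndarray, groups: np.ndarray) -> tuple[float, int, int, float]:
    """One-way between-subjects ANOVA: (F, df1, df2, MSE)."""
    labels = [g for g in GROUP_ORDER if g in set(groups)]
    k = len(labels)
    n_total = len(y)
    means = np.array([y[groups == g].mean() for g in labels])
    ns = np.array([(groups == g).sum() for g in labels])
    grand = y.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((y[groups == g] - m) ** 2) for g, m in zip(labels, means)))
    df1, df2 = k - 1, n_total - k
    mse = ss_within / df2 if df2 > 0 else math.nan
    if mse <= 0 or not np.isfinite(mse):
        return math.nan, df1, df2, mse
    return ss_between / df1 / mse, df1, df2, mse


def _intercept_test(y: np.ndarray, groups: np.ndarray) -> tuple[float, int, int]:
    """Type-III test that the unweighted grand mean of y is zero: (F, 1, N-k)."""
    labels = [g for g in GROUP_ORDER if g in set(groups)]
    k = len(labels)
    n_total = len(y)
    means = np.array([y[groups == g].mean() for g in labels])
    ns = np.array([(groups == g).sum() for g in labels])
    ss_within = float(
        sum(np.sum((y[groups == g] - m) ** 2) for g, m in zip(labels, means))
    )
    df2 = n_total - k
    mse = ss_within / df2 if df2 > 0 else math.nan
    mu = means.mean()
    var_mu = mse * float(np.sum(1.0 / ns)) / k**2
    if not np.isfinite(var_mu) or var_mu <= 0:
        return math.nan, 1, df2
    return mu**2 / var_mu, 1, df2


def _pivot_cells(
    data: pd.DataFrame, parameter: str, within: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Wide table of one value per subject per within-cell, plus group labels.

    Raises with the offending subjects listed if any subject misses a cell.
    """
    d = data[data["parameter"] == parameter]
    if d.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    if "hand" in within:
        d = d[d["hand"].isin(("left", "right"))]
    d = d.dropna(subset=["value"])
    cells = list(itertools.product(*[_WITHIN_LEVELS[f] for f in within])) or [()]
    index_cols = list(within) if within else None
    if within:
        wide = d.pivot_table(
            index="participant_id", columns=list(within), values="value", aggfunc="mean"
        )
        wide = wide.reindex(columns=[c if len(within) > 1 else c[0] for c in cells])
    else:
        wide = d.groupby("participant_id")[["value"]].mean()
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(
            f"subjects with missing cells for {parameter!r}: {incomplete[:10]}"
            + ("..." if len(incomplete) > 10 else "")
        )
    group_of = d.drop_duplicates("participant_id").set_index("participant_id")["group"]
    groups = group_of.reindex(wide.index).to_numpy()
    return wide, groups


def mixed_anova(
    data: pd.DataFrame,
    parameter: str,
    within: Sequence[str] = ("hand", "task"),
    between: str = "group",
) -> pd.DataFrame:
    """Mixed-design ANOVA for one parameter.

    ``data`` is a long table with columns ``participant_id, group, task,
    hand, parameter, value``.  Returns an effect table with one row per
    effect (within and between main effects, all interactions): columns
    ``effect, F, df1, df2, p``.  Complete cases only; subjects with missing
    cells raise.
    """
    if between != "group":
        raise ValueError("the between-subjects factor must be 'group'")
    for f in within:
        if f not in _WITHIN_LEVELS:
            raise ValueError(f"unknown within factor {f!r}")
    wide, groups = _pivot_cells(data, parameter, within)
    values = wide.to_numpy(dtype=float)
    cells = list(itertools.product(*[_WITHIN_LEVELS[f] for f in within])) or [()]

    rows = []
    k_groups = len(set(groups))
    # Between-subjects effect on the subject means.
    if k_groups >= 2:
        subject_mean = values.mean(axis=1)
        f_val, df1, df2, _ = _oneway(subject_mean, groups)
        rows.append(("group", f_val, df1, df2))
    # Each within-effect (every non-empty subset of within factors) reduces
    # to one contrast score per subject.
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            signs = np.array(
                [
                    np.prod(
                        [
                            1.0 if cell[within.index(f)] == _WITHIN_LEVELS[f][1] else -1.0
                            for f in subset
                        ]
                    )
                    for cell in cells
                ]
            )
            contrast = values @ signs / (len(cells) / 2.0)
            name = "*".join(subset)
            f_val, df1, df2 = _intercept_test(contrast, groups)
            rows.append((name, f_val, df1, df2))
            if k_groups >= 2:
                f_val, df1, df2, _ = _oneway(contrast, groups)
                rows.append((f"{name}*group", f_val, df1, df2))
    out = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2"])
    out["p"] = stats.f.sf(out["F"], out["df1"], out["df2"])
    return out


def two_way_mixed_anova(
    data: pd.DataFrame, parameter: str = "sd_phase_difference"
) -> pd.DataFrame:
    """Group x task mixed ANOVA (used for the phase-difference SD, which has
    no hand factor)."""
    return mixed_anova(data, parameter, within=("task",))


# ---------------------------------------------------------------------------
# Bonferroni post-hoc tests
# ---------------------------------------------------------------------------


def pairwise_group_tests(
    values: Mapping[str, np.ndarray], adjust: bool = True
) -> pd.DataFrame:
    """All pairwise group contrasts with a pooled error term.

    Uses the pooled within-group variance over *all* supplied groups
    (df = N - k) for every contrast, and Bonferroni-adjusts by the number of
    contrasts.  Returns columns ``a, b, diff, t, df, p_raw, p_adj``.
    """
    labels = [g for g in GROUP_ORDER if g in values] or list(values)
    arrays = {g: np.asarray(values[g], dtype=float) for g in labels}
    ns = {g: len(a) for g, a in arrays.items()}
    if any(n < 2 for n in ns.values()):
        raise ValueError("every group needs >= 2 observations")
    n_total = sum(ns.values())
    k = len(labels)
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()) / (n_total - k)
    pairs = list(itertools.combinations(labels, 2))
    family = len(pairs)
    rows = []
    for a, b in pairs:
        diff = arrays[a].mean() - arrays[b].mean()
        se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b])) if mse > 0 else math.nan
        t = diff / se if se and np.isfinite(se) and se > 0 else math.nan
        df = n_total - k
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else math.nan
        p_adj = min(1.0, p * family) if adjust and np.isfinite(p) else p
        rows.append((a, b, diff, t, df, p, p_adj))
    return pd.DataFrame(rows, columns=["a", "b", "diff", "t", "df", "p_raw", "p_adj"])


def _paired_contrast(diff: np.ndarray) -> tuple[float, float, int, float]:
    """Paired t-test of a within-subject difference against zero."""
    n = len(diff)
    if n < 2:
        return math.nan, math.nan, n - 1, math.nan
    se = diff.std(ddof=1) / math.sqrt(n)
    if se == 0:
        return float(diff.mean()), math.nan, n - 1, math.nan
    t = diff.mean() / se
    return float(diff.mean()), float(t), n - 1, float(2.0 * stats.t.sf(abs(t), n - 1))


def bonferroni_posthoc(
    data: pd.DataFrame,
    parameter: str,
    effect: str,
    effect_table: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    enforce_gate: bool = True,
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise comparisons for a significant effect.

    For ``group``: one family of all pairwise group contrasts on the
    subject means.  For a two-level within factor: the single paired
    contrast.  For a ``within*group`` interaction: simple effects in both
    directions -- group contrasts within each level (family = number of
    pairs) and the paired level contrast within each group (family = 1
    each).  Adjusted p-values are ``min(1, raw * family)``.

    Refuses (raises ``ValueError``) when the requested effect is not
    significant in ``effect_table`` and ``enforce_gate`` is set.
    """
    if enforce_gate:
        if effect_table is None:
            raise ValueError("effect_table is required to check significance")
        row = effect_table[effect_table["effect"] == effect]
        if row.empty:
            raise ValueError(f"effect {effect!r} not present in the effect table")
        if not (row["p"].iloc[0] < alpha):
            raise ValueError(
                f"effect {effect!r} is not significant (p={row['p'].iloc[0]:.3g}); "
                "post-hoc tests refused"
            )

    factors = effect.split("*")
    within_factors = [f for f in factors if f in _WITHIN_LEVELS]
    has_group = "group" in factors
    # Pivot on every within factor present for this parameter.
    present = tuple(
        f
        for f in ("hand", "task")
        if f in data.columns
        and data.loc[data["parameter"] == parameter, f].isin(_WITHIN_LEVELS[f]).any()
    )
    wide, groups = _pivot_cells(data, parameter, present)
    cells = list(itertools.product(*[_WITHIN_LEVELS[f] for f in present])) or [()]
    values = wide.to_numpy(dtype=float)

    def level_mean(factor: str, level: str) -> np.ndarray:
        idx = [
            i for i, cell in enumerate(cells) if cell[present.index(factor)] == level
        ]
        return values[:, idx].mean(axis=1)

    rows: list[dict[str, object]] = []

    def add_group_family(y: np.ndarray, context: str) -> None:
        by_group = {g: y[groups == g] for g in sorted(set(groups), key=GROUP_ORDER.index)}
        table = pairwise_group_tests(by_group)
        for r in table.itertuples(index=False):
            rows.append(
                {
                    "context": context,
                    "contrast": f"{r.a} - {r.b}",
                    "family": len(table),
                    "estimate": r.diff,
                    "t": r.t,
                    "df": r.df,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                }
            )

    def add_paired(factor: str, mask: np.ndarray, context: str) -> None:
        lo, hi = _WITHIN_LEVELS[factor]
        diff = (level_mean(factor, hi) - level_mean(factor, lo))[mask]
        est, t, df, p = _paired_contrast(diff)
        rows.append(
            {
                "context": context,
                "contrast": f"{factor}:{hi} - {factor}:{lo}",
                "family": 1,
                "estimate": est,
                "t": t,
                "df": df,
                "p_raw": p,
                "p_adj": p,
            }
        )

    everyone = np.ones(len(values), dtype=bool)
    if factors == ["group"]:
        add_group_family(values.mean(axis=1), "all")
    elif len(factors) == 1 and within_factors:
        add_paired(within_factors[0], everyone, "all")
    elif has_group and len(within_factors) == 1:
        f = within_factors[0]
        for level in _WITHIN_LEVELS[f]:
            add_group_family(level_mean(f, level), f"{f}={level}")
        for g in sorted(set(groups), key=GROUP_ORDER.index):
            add_paired(f, groups == g, f"group={g}")
    elif not has_group and len(within_factors) == 2:
        f1, f2 = within_factors
        for level in _WITHIN_LEVELS[f2]:
            idx = [i for i, cell in enumerate(cells) if cell[present.index(f2)] == level]
            lo_i = [i for i in idx if cells[i][present.index(f1)] == _WITHIN_LEVELS[f1][0]]
            hi_i = [i for i in idx if cells[i][present.index(f1)] == _WITHIN_LEVELS[f1][1]]
            diff = values[:, hi_i].mean(axis=1) - values[:, lo_i].mean(axis=1)
            est, t, df, p = _paired_contrast(diff)
            rows.append(
                {
                    "context": f"{f2}={level}",
                    "contrast": f"{f1}:{_WITHIN_LEVELS[f1][1]} - {f1}:{_WITHIN_LEVELS[f1][0]}",
                    "family": 1,
                    "estimate": est,
                    "t": t,
                    "df": df,
                    "p_raw": p,
                    "p_adj": p,
                }
            )
    elif has_group and len(within_factors) == 2:
        # Three-way interaction: group contrasts within each within-cell.
        for cell in cells:
            idx = [i for i, c in enumerate(cells) if c == cell]
            context = ",".join(f"{f}={v}" for f, v in zip(present, cell))
            add_group_family(values[:, idx].mean(axis=1), context)
    else:
        raise ValueError(f"unsupported effect {effect!r}")

    out = pd.DataFrame(rows)
    out.insert(0, "parameter", parameter)
    out.insert(1, "effect", effect)
    out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# Correlations and screening eligibility
# ---------------------------------------------------------------------------


def pearson_age_correlations(data: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-sided p) between age and every (task, hand,
    parameter) cell; cells with fewer than 3 pairs or zero variance give
    NaN markers."""
    rows = []
    for (task, hand, parameter), d in data.dropna(subset=["value"]).groupby(
        ["task", "hand", "parameter"], sort=True
    ):
        d = d.drop_duplicates("participant_id")
        age = d["age"].to_numpy(dtype=float)
        val = d["value"].to_numpy(dtype=float)
        if len(d) < 3 or np.std(age) == 0 or np.std(val) == 0:
            r, p = math.nan, math.nan
        else:
            r, p = stats.pearsonr(age, val)
        rows.append(
            {
                "task": task,
                "hand": hand,
                "parameter": parameter,
                "n": len(d),
                "r": float(r),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def parameters_distinguishing_all_groups(
    data: pd.DataFrame,
    alpha: float = 0.05,
    parameters: Optional[Iterable[str]] = None,
) -> list[str]:
    """Parameters whose Bonferroni pairwise group contrasts are all
    significant in *both* tasks (hands averaged where applicable) -- the
    eligibility rule for the age-cutoff ROC panel."""
    if parameters is None:
        parameters = list(HAND_PARAMETERS) + ["sd_phase_difference"]
    eligible = []
    for parameter in parameters:
        ok = True
        for task in ("in_phase", "anti_phase"):
            d = data[(data["parameter"] == parameter) & (data["task"] == task)]
            d = d.dropna(subset=["value"])
            if d.empty:
                ok = False
                break
            per_subject = d.groupby(["participant_id", "group"])["value"].mean().reset_index()
            by_group = {
                g: per_subject.loc[per_subject["group"] == g, "value"].to_numpy()
                for g in GROUP_ORDER
                if (per_subject["group"] == g).any()
            }
            if len(by_group) < 3:
                ok = False
                break
            table = pairwise_group_tests(by_group)
            if not (table["p_adj"] < alpha).all():
                ok = False
                break
        if ok:
            eligible.append(parameter)
    return eligible
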