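"""Published ROC reference panel for the bimanual tapping age cutoffs.

The screening study this package reimplements reports, for the three
parameters that separated all age groups (number of taps, average tapping
interval, tap frequency), one ROC row per task x hand: AUC with its
standard error, the Youden-optimal age cutoff, the 95% CI, and sensitivity
/ specificity (%) with the Youden index.  These printed values serve as
inputs for arithmetic consistency checks (Youden identity, CI
reconstruction); the underlying raw data are not public, so the panel is
not a target the simulator is fitted to.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_roc_panel"]

_ROWS = [
    # parameter, task, hand, auc, auc_se, cutoff, ci_lo, ci_hi, sn_pct, sp_pct, yi
    ("number_of_taps", "in_phase", "left", 0.68, 0.026, 72.5, 0.63, 0.74, 77.5, 54.8, 0.32),
    ("number_of_taps", "in_phase", "right", 0.68, 0.026, 72.5, 0.63, 0.73, 77.0, 54.8, 0.32),
    ("number_of_taps", "anti_phase", "left", 0.73, 0.025, 65.5, 0.68, 0.78, 93.8, 44.8, 0.39),
    ("number_of_taps", "anti_phase", "right", 0.73, 0.026, 68.5, 0.68, 0.78, 89.0, 50.5, 0.40),
    ("ave_tapping_interval", "in_phase", "left", 0.67, 0.026, 72.5, 0.62, 0.72, 81.3, 51.5, 0.33),
    ("ave_tapping_interval", "in_phase", "right", 0.68, 0.026, 72.5, 0.63, 0.73, 81.4, 51.7, 0.33),
    ("ave_tapping_interval", "anti_phase", "left", 0.72, 0.025, 73.5, 0.67, 0.77, 78.4, 57.6, 0.36),
    ("ave_tapping_interval", "anti_phase", "right", 0.72, 0.025, 73.5, 0.67, 0.77, 78.7, 58.0, 0.37),
    ("frequency_of_taps", "in_phase", "left", 0.68, 0.026, 72.5, 0.63, 0.73, 77.3, 54.3, 0.32),
    ("frequency_of_taps", "in_phase", "right", 0.68, 0.026, 72.5, 0.63, 0.73, 77.2, 54.8, 0.32),
    ("frequency_of_taps", "anti_phase", "left", 0.72, 0.026, 65.5, 0.67, 0.77, 93.8, 44.6, 0.38),
    ("frequency_of_taps", "anti_phase", "right", 0.71, 0.026, 70.5, 0.66, 0.77, 84.8, 52.9, 0.38),
]

_COLUMNS = [
    "parameter",
    "task",
    "hand",
    "auc",
    "auc_se",
    "cutoff_years",
    "ci_lower",
    "ci_upper",
    "sensitivity_pct",
    "specificity_pct",
    "youden_index",
]


def reference_roc_panel() -> pd.DataFrame:
    """The published 12-row ROC panel as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
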