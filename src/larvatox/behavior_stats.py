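"""Group statistics for QC-passed photomotor-response traces.

The unit of analysis is the per-larva phase mean (mean distance per bin over
all light bins, and separately over all dark bins), which avoids
pseudo-replicating the 240 bins. Light and dark are analyzed as separate
families: one-way ANOVA across groups followed by Tukey's HSD all-pairs
procedure, reported filtered to each group vs control, significance at
α = 0.05. A Shapiro–Wilk normality check is provided as a diagnostic only —
it never gates the ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .behavior_qc import DARK, LIGHT, LocomotionTrace
from .exceptions import DegenerateDataError, InsufficientDataWarning, ValidationError

SUMMARY_COLUMNS = ["larva_id", "group", "mean_distance_light", "mean_distance_dark"]


def summarize_movement(traces: Sequence[LocomotionTrace]) -> pd.DataFrame:
    """Per-larva mean distance per bin, separately for light and dark phases."""
    if not traces:
        warnings.warn("no traces to summarize", InsufficientDataWarning)
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    rows = [
        {
            "larva_id": t.larva_id,
            "group": t.group,
            "mean_distance_light": float(np.mean(t.phase_values(LIGHT))),
            "mean_distance_dark": float(np.mean(t.phase_values(DARK))),
        }
        for t in traces
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p for a sample of 3–5000 values (diagnostic only)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 3 or values.size > 5000:
        raise ValidationError(
            f"Shapiro–Wilk requires 3 ≤ n ≤ 5000, got n = {values.size}"
        )
    w, p = stats.shapiro(values)
    return float(w), float(p)


@dataclass
class BehaviorTestResult:
    """ANOVA + Tukey-vs-control results for one phase type."""

    phase_type: str
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # group, mean_diff, p_adj, significant, direction
    alpha: float = 0.05


def compare_groups(
    summary: pd.DataFrame,
    control_label: str,
    phase_type: str,
    alpha: float = 0.05,
) -> BehaviorTestResult:
    """One-way ANOVA across all groups plus Tukey HSD filtered to vs-control.

    ``direction`` labels each non-control group hypo (mean below control) or
    hyper. Requires ≥ 2 groups including the control, ≥ 2 larvae per group,
    and non-zero within-group variance overall.
    """
    if phase_type not in (LIGHT, DARK):
        raise ValidationError(f"phase_type must be '{LIGHT}' or '{DARK}'")
    column = f"mean_distance_{phase_type}"
    if column not in summary.columns:
        raise ValidationError(f"summary lacks column {column!r}")
    groups = list(dict.fromkeys(summary["group"]))
    if control_label not in groups:
        raise ValidationError(f"control group {control_label!r} not in summary")
    if len(groups) < 2:
        raise DegenerateDataError("need at least 2 groups for ANOVA")
    samples = {g: summary.loc[summary["group"] == g, column].to_numpy() for g in groups}
    if any(len(v) < 2 for v in samples.values()):
        raise DegenerateDataError("need at least 2 larvae per group")
    if all(np.var(v) == 0 for v in samples.values()):
        raise DegenerateDataError("zero within-group variance in every group")

    f_stat, p_value = stats.f_oneway(*samples.values())

    tukey = pairwise_tukeyhsd(
        endog=summary[column].to_numpy(),
        groups=summary["group"].to_numpy(),
        alpha=alpha,
    )
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    control_mean = float(np.mean(samples[control_label]))
    rows = []
    for _, row in tukey_df.iterrows():
        pair = {str(row["group1"]), str(row["group2"])}
        if control_label not in pair or len(pair) == 1:
            continue
        other = (pair - {control_label}).pop()
        diff = float(np.mean(samples[other])) - control_mean
        p_adj = float(row["p-adj"])
        rows.append(
            {
                "group": other,
                "mean_diff": diff,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
                "direction": "hypo" if diff < 0 else "hyper",
            }
        )
    pairwise = pd.DataFrame(rows, columns=["group", "mean_diff", "p_adj", "significant", "direction"])
    return BehaviorTestResult(
        phase_type=phase_type,
        anova_F=float(f_stat),
        anova_p=float(p_value),
        pairwise=pairwise,
        alpha=alpha,
    )
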