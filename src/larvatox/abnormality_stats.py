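"""Endpoint screening statistics: chi-square with Bonferroni pairwise tests.

For one endpoint at one timepoint/duration, the affected/unaffected counts
across concentration groups form a 2 × k table. The global test is an
uncorrected Pearson chi-square (df = k − 1); each non-control concentration
is then compared to the control in a 2 × 2 chi-square, with Bonferroni
adjustment over the m non-control comparisons (p_adj = min(1, m·p)) at
α = 0.05. Groups whose cumulative mortality reaches 100% by the final
screening timepoint are gated out as non-evaluable.

Denominator convention: abnormality endpoints are counted among survivors at
the screening timepoint; mortality among all embryos (so the dead are never
counted as "not abnormal").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateDataError,
    LowExpectedCountWarning,
    ValidationError,
)

SCREENING_COLUMNS = [
    "endpoint",
    "chemical",
    "concentration_nM",
    "duration",
    "timepoint_hpf",
    "n_affected",
    "n_total",
]

#: endpoint → default analysis timepoint (hpf); unhatched is scored before
#: the end of the assay because hatching normally completes by ~72 hpf.
DEFAULT_TIMEPOINTS = {"unhatched": 72}
FINAL_TIMEPOINT = 120


def validate_screening_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SCREENING_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"screening table missing columns: {sorted(missing)}")
    bad = table[(table["n_affected"] < 0) | (table["n_affected"] > table["n_total"])]
    if len(bad):
        raise ValidationError("n_affected must satisfy 0 ≤ n_affected ≤ n_total")
    return table


def global_chi_square(
    affected: np.ndarray, totals: np.ndarray, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2 × k affected/unaffected table.

    Returns (chi2, df, p). Raises on a degenerate margin (all affected or
    none affected, or an empty group); warns when any expected count < 5.
    """
    affected = np.asarray(affected, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if affected.size < 2:
        raise DegenerateDataError("need at least 2 groups")
    if np.any(totals <= 0):
        raise DegenerateDataError("every group must have n_total > 0")
    unaffected = totals - affected
    table = np.vstack([affected, unaffected])
    if np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("a margin of the table is all zero")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 5):
        warnings.warn(
            "chi-square expected count below 5; test computed anyway",
            LowExpectedCountWarning,
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), int(df), float(p)


@dataclass
class EndpointTestResult:
    """Global + pairwise chi-square results for one endpoint slice."""

    endpoint: str
    global_chi2: float
    df: int
    global_p: float
    pairwise: pd.DataFrame  # concentration_nM, chi2, raw_p, p_adj, significant
    m: int
    alpha: float = 0.05


def pairwise_vs_control(
    slice_df: pd.DataFrame,
    control_concentration: float = 0.0,
    alpha: float = 0.05,
    yates: bool = False,
) -> EndpointTestResult:
    """Global chi-square plus Bonferroni-corrected 2×2 tests vs control.

    ``slice_df`` is one endpoint × duration × timepoint slice of a screening
    table (one row per concentration).
    """
    validate_screening_table(slice_df)
    endpoints = slice_df["endpoint"].unique()
    if len(endpoints) != 1:
        raise ValidationError("slice must contain exactly one endpoint")
    slice_df = slice_df.sort_values("concentration_nM")
    concentrations = slice_df["concentration_nM"].to_numpy(dtype=float)
    if control_concentration not in concentrations:
        raise ValidationError(
            f"control concentration {control_concentration} absent from slice"
        )
    affected = slice_df["n_affected"].to_numpy(dtype=float)
    totals = slice_df["n_total"].to_numpy(dtype=float)

    chi2, df, p = global_chi_square(affected, totals, yates=yates)

    ctrl = concentrations == control_concentration
    ctrl_aff, ctrl_tot = float(affected[ctrl][0]), float(totals[ctrl][0])
    others = np.flatnonzero(~ctrl)
    m = len(others)
    rows = []
    for i in others:
        pair_chi2, _, pair_p = global_chi_square(
            np.array([ctrl_aff, affected[i]]), np.array([ctrl_tot, totals[i]]), yates=yates
        )
        p_adj = bonferroni(pair_p, m)
        rows.append(
            {
                "concentration_nM": concentrations[i],
                "chi2": pair_chi2,
                "raw_p": pair_p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    pairwise = pd.DataFrame(
        rows, columns=["concentration_nM", "chi2", "raw_p", "p_adj", "significant"]
    )
    return EndpointTestResult(
        endpoint=str(endpoints[0]),
        global_chi2=chi2,
        df=df,
        global_p=p,
        pairwise=pairwise,
        m=m,
        alpha=alpha,
    )


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m × p)."""
    if m < 1:
        raise ValidationError("number of comparisons must be ≥ 1")
    return min(1.0, m * raw_p)


def mortality_gate(table: pd.DataFrame) -> pd.DataFrame:
    """Mark 100%-mortality conditions as non-evaluable.

    A condition (chemical × concentration × duration) whose cumulative
    mortality equals its total at the final screening timepoint cannot be
    evaluated for abnormalities or behavior downstream. The gate fires at
    100% only.
    """
    if table.empty:
        return pd.DataFrame(columns=["chemical", "concentration_nM", "duration", "evaluable", "reason"])
    validate_screening_table(table)
    mort = table[table["endpoint"] == "mortality"]
    rows = []
    for (chem, conc, dur), sub in mort.groupby(
        ["chemical", "concentration_nM", "duration"], sort=False
    ):
        final = sub.loc[sub["timepoint_hpf"].idxmax()]
        dead_all = final["n_total"] > 0 and final["n_affected"] == final["n_total"]
        rows.append(
            {
                "chemical": chem,
                "concentration_nM": conc,
                "duration": dur,
                "evaluable": not dead_all,
                "reason": (
                    f"100% mortality by {int(final['timepoint_hpf'])} hpf" if dead_all else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def analyze_endpoints(
    table: pd.DataFrame,
    control_concentration: float = 0.0,
    alpha: float = 0.05,
    yates: bool = False,
    timepoints: dict[str, int] | None = None,
) -> dict[tuple[str, str, str], EndpointTestResult]:
    """Run global + pairwise tests for every endpoint × chemical × duration.

    Abnormality endpoints default to the final (120 hpf) cumulative
    screening, except "unhatched" at 72 hpf; overridable per endpoint via
    ``timepoints``. Non-evaluable (100%-mortality) conditions are dropped
    before testing.
    """
    validate_screening_table(table)
    timepoints = {**DEFAULT_TIMEPOINTS, **(timepoints or {})}
    gate = mortality_gate(table)
    blocked = {
        (r["chemical"], r["concentration_nM"], r["duration"])
        for _, r in gate.iterrows()
        if not r["evaluable"]
    }
    is_control_row = table["concentration_nM"] == control_concentration
    chemicals = [c for c in table.loc[~is_control_row, "chemical"].unique()]
    results: dict[tuple[str, str, str], EndpointTestResult] = {}
    for chem in chemicals:
        for (endpoint, dur), sub in table[
            (table["chemical"] == chem) & ~is_control_row
        ].groupby(["endpoint", "duration"], sort=False):
            t = timepoints.get(endpoint, FINAL_TIMEPOINT)
            controls = table[
                is_control_row
                & (table["endpoint"] == endpoint)
                & (table["duration"] == dur)
                & (table["timepoint_hpf"] == t)
            ]
            at_t = pd.concat([controls, sub[sub["timepoint_hpf"] == t]])
            if endpoint != "mortality":
                at_t = at_t[
                    [
                        (r["chemical"], r["concentration_nM"], r["duration"]) not in blocked
                        for _, r in at_t.iterrows()
                    ]
                ]
            if len(at_t) < 2 or control_concentration not in set(at_t["concentration_nM"]):
                continue
            try:
                results[(endpoint, chem, dur)] = pairwise_vs_control(
                    at_t, control_concentration, alpha=alpha, yates=yates
                )
            except DegenerateDataError:
                continue
    return results
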