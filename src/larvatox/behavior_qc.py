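"""Larval photomotor-response quality control.

Larval zebrafish normally swim more in the dark than in the light
(scototaxis-driven photomotor response). Traces that violate this pattern,
or that contain bursts of implausibly large movement in the light phases,
are removed before group statistics by three per-larva rules:

1. **Light serial-exceedance rule** — within a trace's own light-phase bins,
   compute the Tukey fence ``T = Q3 + k·IQR`` (default k = 1.5). The trace is
   flagged if ``serial_run_length`` consecutive light bins (default 2), each
   past a per-phase burn-in (default 60 s, skipping transition startle
   artifacts), all exceed T strictly.
2. **Dark below-median rule** — flagged if ``serial_run_length`` consecutive
   dark bins each fall strictly below the median of the trace's light bins.
3. **Light:dark ratio rule** — flagged if mean(light)/mean(dark) ≥ 0.9
   (boundary inclusive): a non-responder moving nearly as much in light as
   in dark.

All rules are per-trace functions of that trace alone, so QC is idempotent
and unaffected by cohort composition. Quantiles use linear interpolation
between order statistics (numpy default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateRatioWarning,
    InsufficientDataWarning,
    MalformedTraceError,
    ValidationError,
)

LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """Alternating light/dark protocol of the behavioral assay.

    Defaults are the assay's protocol: 3-min phases, four light-dark cycles
    (24 min), 6-s integration bins, starting in light after light acclimation
    → 8 phases × 30 bins = 240 bins.
    """

    phase_length_s: int = 180
    n_cycles: int = 4
    bin_width_s: int = 6
    first_phase: str = LIGHT

    def __post_init__(self) -> None:
        if self.phase_length_s <= 0 or self.n_cycles <= 0 or self.bin_width_s <= 0:
            raise ValidationError("schedule fields must be positive")
        if self.phase_length_s % self.bin_width_s != 0:
            raise ValidationError("phase_length_s must be divisible by bin_width_s")
        if self.first_phase not in (LIGHT, DARK):
            raise ValidationError(f"first_phase must be '{LIGHT}' or '{DARK}'")

    @property
    def bins_per_phase(self) -> int:
        return self.phase_length_s // self.bin_width_s

    @property
    def n_phases(self) -> int:
        return 2 * self.n_cycles

    @property
    def n_bins(self) -> int:
        return self.n_phases * self.bins_per_phase

    @property
    def total_duration_s(self) -> int:
        return 2 * self.n_cycles * self.phase_length_s

    def phase_index(self, bin_index: int) -> int:
        return (bin_index * self.bin_width_s) // self.phase_length_s

    def phase_labels(self) -> np.ndarray:
        """Label per bin: alternating phases starting from ``first_phase``."""
        idx = np.arange(self.n_bins) // self.bins_per_phase
        other = DARK if self.first_phase == LIGHT else LIGHT
        return np.where(idx % 2 == 0, self.first_phase, other)

    def within_phase_elapsed_s(self) -> np.ndarray:
        """Elapsed time at the END of each bin, measured from its phase start."""
        within = np.arange(self.n_bins) % self.bins_per_phase
        return (within + 1) * self.bin_width_s


@dataclass
class LocomotionTrace:
    """One larva's distance-moved series (cm per bin) with phase labels."""

    larva_id: str
    group: str
    distance_cm: np.ndarray
    schedule: PhotoperiodSchedule

    def __post_init__(self) -> None:
        self.distance_cm = np.asarray(self.distance_cm, dtype=float)
        if self.distance_cm.ndim != 1 or len(self.distance_cm) != self.schedule.n_bins:
            raise MalformedTraceError(
                f"trace {self.larva_id!r}: {len(self.distance_cm)} bins, "
                f"schedule expects {self.schedule.n_bins}"
            )
        if not np.all(np.isfinite(self.distance_cm)):
            raise MalformedTraceError(f"trace {self.larva_id!r}: non-finite distances")
        if np.any(self.distance_cm < 0):
            raise MalformedTraceError(f"trace {self.larva_id!r}: negative distances")

    @property
    def phase(self) -> np.ndarray:
        return self.schedule.phase_labels()

    def phase_values(self, phase: str) -> np.ndarray:
        return self.distance_cm[self.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        sched = self.schedule
        return pd.DataFrame(
            {
                "larva_id": self.larva_id,
                "group": self.group,
                "bin_index": np.arange(sched.n_bins),
                "time_s": np.arange(sched.n_bins) * sched.bin_width_s,
                "phase": self.phase,
                "distance_cm": self.distance_cm,
            }
        )


def label_phases(
    distances: Sequence[float],
    schedule: PhotoperiodSchedule,
    larva_id: str = "larva",
    group: str = "unknown",
) -> LocomotionTrace:
    """Attach photoperiod phase labels to a raw bin series.

    Bin i (0-based) belongs to phase ``floor(i × bin_width / phase_length)``.
    """
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        raise MalformedTraceError("empty bin series")
    return LocomotionTrace(larva_id, group, distances, schedule)


@dataclass(frozen=True)
class QCThresholds:
    """Tunables of the three exclusion rules (defaults = assay protocol)."""

    iqr_multiplier: float = 1.5
    serial_run_length: int = 2
    light_burn_in_s: float = 60.0
    ratio_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if (
            self.iqr_multiplier <= 0
            or self.serial_run_length <= 0
            or self.light_burn_in_s < 0
            or self.ratio_cutoff <= 0
        ):
            raise ValidationError("QC thresholds must be strictly positive")


def _has_serial_run(ok: np.ndarray, phase_idx: np.ndarray, run: int) -> bool:
    """True if `run` consecutive bins (same phase, adjacent indices) all
    satisfy ``ok``."""
    if run == 1:
        return bool(ok.any())
    n = len(ok)
    if n < run:
        return False
    window = np.ones(n - run + 1, dtype=bool)
    for j in range(run):
        window &= ok[j : n - run + 1 + j]
    window &= phase_idx[run - 1 :] == phase_idx[: n - run + 1]
    return bool(window.any())


def light_serial_exceedance_flag(
    trace: LocomotionTrace, thresholds: QCThresholds = QCThresholds()
) -> tuple[bool, float]:
    """Apply the light-cycle IQR serial-exceedance rule.

    Returns ``(flag, fence)`` where fence = Q3 + k·IQR over this trace's
    light bins. Only bins whose within-phase elapsed time exceeds the
    burn-in participate in the run search; exceedance is strict.
    """
    light_mask = trace.phase == LIGHT
    values = trace.distance_cm[light_mask]
    if values.size < 4:
        warnings.warn(
            f"trace {trace.larva_id!r}: fewer than 4 light bins; light rule skipped",
            InsufficientDataWarning,
        )
        return False, float("nan")
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    fence = q3 + thresholds.iqr_multiplier * (q3 - q1)

    all_bins = np.arange(trace.schedule.n_bins)
    elapsed = trace.schedule.within_phase_elapsed_s()
    phase_idx = all_bins // trace.schedule.bins_per_phase
    eligible = light_mask & (elapsed > thresholds.light_burn_in_s)
    exceeds = trace.distance_cm > fence
    flag = _has_serial_run(eligible & exceeds, phase_idx, thresholds.serial_run_length)
    return flag, float(fence)


def dark_below_median_flag(
    trace: LocomotionTrace, thresholds: QCThresholds = QCThresholds()
) -> tuple[bool, float]:
    """Apply the dark-cycle below-light-median rule.

    Returns ``(flag, light_median)``; flagged when ``serial_run_length``
    consecutive dark bins each fall strictly below the light median.
    """
    light = trace.phase_values(LIGHT)
    dark_mask = trace.phase == DARK
    if light.size < 1 or dark_mask.sum() < thresholds.serial_run_length:
        warnings.warn(
            f"trace {trace.larva_id!r}: missing phases for dark rule",
            InsufficientDataWarning,
        )
        return False, float("nan")
    median = float(np.median(light))
    phase_idx = np.arange(trace.schedule.n_bins) // trace.schedule.bins_per_phase
    below = trace.distance_cm < median
    flag = _has_serial_run(dark_mask & below, phase_idx, thresholds.serial_run_length)
    return flag, median


def light_dark_ratio_flag(
    trace: LocomotionTrace, thresholds: QCThresholds = QCThresholds()
) -> tuple[bool, float]:
    """Apply the light:dark mean-ratio non-responder rule (boundary inclusive)."""
    light_mean = float(np.mean(trace.phase_values(LIGHT)))
    dark_mean = float(np.mean(trace.phase_values(DARK)))
    if dark_mean == 0:
        warnings.warn(
            f"trace {trace.larva_id!r}: zero dark movement; ratio undefined, "
            "treated as non-responder",
            DegenerateRatioWarning,
        )
        return True, float("inf")
    ratio = light_mean / dark_mean
    return ratio >= thresholds.ratio_cutoff, ratio


@dataclass
class QCReport:
    """Per-trace rule flags/thresholds and per-group retention counts."""

    per_trace: pd.DataFrame
    thresholds: QCThresholds

    @property
    def retention(self) -> pd.DataFrame:
        g = self.per_trace.groupby("group", sort=False)["excluded"]
        out = g.agg(n_input="size", n_excluded="sum").reset_index()
        out["n_retained"] = out["n_input"] - out["n_excluded"]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": {
                "iqr_multiplier": self.thresholds.iqr_multiplier,
                "serial_run_length": self.thresholds.serial_run_length,
                "light_burn_in_s": self.thresholds.light_burn_in_s,
                "ratio_cutoff": self.thresholds.ratio_cutoff,
                "quantile_rule": "linear interpolation between order statistics",
            },
            "per_trace": self.per_trace.to_dict(orient="records"),
            "retention": self.retention.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.per_trace.to_csv(path, index=False)


def apply_qc(
    traces: Sequence[LocomotionTrace], thresholds: QCThresholds = QCThresholds()
) -> tuple[list[LocomotionTrace], QCReport]:
    """Evaluate all three rules on every trace; exclude if any rule fires.

    Rules are evaluated independently (no short-circuit) so the report always
    shows all three flags. All traces must share one schedule.
    """
    schedules = {t.schedule for t in traces}
    if len(schedules) > 1:
        raise ValidationError("all traces must share one photoperiod schedule")
    rows = []
    retained: list[LocomotionTrace] = []
    for trace in traces:
        light_flag, fence = light_serial_exceedance_flag(trace, thresholds)
        dark_flag, median = dark_below_median_flag(trace, thresholds)
        ratio_flag, ratio = light_dark_ratio_flag(trace, thresholds)
        excluded = light_flag or dark_flag or ratio_flag
        rows.append(
            {
                "larva_id": trace.larva_id,
                "group": trace.group,
                "light_rule_flag": light_flag,
                "light_fence": fence,
                "dark_rule_flag": dark_flag,
                "light_median": median,
                "ratio_flag": ratio_flag,
                "light_dark_ratio": ratio,
                "excluded": excluded,
            }
        )
        if not excluded:
            retained.append(trace)
    report = QCReport(per_trace=pd.DataFrame(rows), thresholds=thresholds)
    return retained, report


# ---------------------------------------------------------------------------
# I/O

TRACE_COLUMNS = ["larva_id", "group", "bin_index", "time_s", "phase", "distance_cm"]


def traces_to_frame(traces: Iterable[LocomotionTrace]) -> pd.DataFrame:
    frames = [t.to_frame() for t in traces]
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: Iterable[LocomotionTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path, schedule: PhotoperiodSchedule) -> list[LocomotionTrace]:
    """Read tidy trace CSV (one row per larva × bin) back into traces."""
    df = pd.read_csv(path)
    missing = {"larva_id", "bin_index", "distance_cm"} - set(df.columns)
    if missing:
        raise ValidationError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for larva_id, sub in df.groupby("larva_id", sort=False):
        sub = sub.sort_values("bin_index")
        group = str(sub["group"].iloc[0]) if "group" in sub else "unknown"
        traces.append(
            LocomotionTrace(str(larva_id), group, sub["distance_cm"].to_numpy(), schedule)
        )
    return traces


def read_traces_wide(
    path: str | Path,
    schedule: PhotoperiodSchedule,
    group: str = "unknown",
) -> list[LocomotionTrace]:
    """Read a tracker-style wide export: one column per larva, one row per bin."""
    df = pd.read_csv(path)
    return [
        LocomotionTrace(str(col), group, df[col].to_numpy(dtype=float), schedule)
        for col in df.columns
    ]
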