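"""Seeded synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's three input kinds:

* :func:`simulate_traces` — per-larva locomotion traces over the light/dark
  protocol (24 larvae/group by default), with optional planted bin outliers
  and planted non-responders.
* :func:`simulate_screening` — abnormality/mortality count tables
  (150 embryos per condition by default) from per-larva Bernoulli states and
  a constant per-interval death hazard.
* :func:`simulate_deg_table` — genome-scale per-gene DE result tables with
  planted true DEGs, including genes planted as shared across chemical sets,
  and Benjamini–Hochberg adjusted p-values per condition.

Determinism: each generator draws from its own RNG stream derived from the
master seed (``default_rng([seed, salt])``), so identical configs give
bit-identical outputs and adding one generator never perturbs another.
Distance noise is truncated normal (clipped at 0) on the bin scale; bins are
independent given phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .behavior_qc import DARK, LIGHT, LocomotionTrace, PhotoperiodSchedule
from .exceptions import ConfigurationError

_TRACE_SALT = 101
_SCREEN_SALT = 202
_DEG_SALT = 303

#: screening endpoints; "total_abnormalities" is derived, not drawn.
MORPH_ENDPOINTS = (
    "skeletal",
    "uninflated_swim_bladder",
    "yolk_sac_edema",
    "cardiac_edema",
)
ENDPOINTS = ("mortality", "unhatched") + MORPH_ENDPOINTS + ("total_abnormalities",)
TIMEPOINTS_HPF = (24, 48, 72, 96, 120)


@dataclass(frozen=True)
class GroupSpec:
    """One exposure condition: chemical × concentration × duration."""

    chemical: str
    concentration_nM: float
    duration: str = "120h"
    effect_multiplier_dark: float = 1.0
    effect_multiplier_light: float = 1.0

    @property
    def label(self) -> str:
        return f"{self.chemical}:{self.concentration_nM:g}nM:{self.duration}"

    @property
    def is_control(self) -> bool:
        return self.concentration_nM == 0


def default_groups() -> tuple[GroupSpec, ...]:
    return (
        GroupSpec("vehicle", 0.0, "120h"),
        GroupSpec("triclosan", 10.0, "120h"),
    )


@dataclass
class SimulationConfig:
    """All knobs of the three generators; one master seed governs everything.

    Behavioral defaults reflect the assay's structure: 24 larvae per group,
    dark-phase baseline 1.2 cm/bin vs light 0.4 cm/bin (the normal dark
    hyperactivity pattern, light:dark ratio ≈ 0.33), 25% bin-level noise CV.
    Screening defaults use 150 embryos per condition. DE tables default to
    5000 genes with 50 planted DEGs per condition at |log2FC| ≈ 1.5.
    """

    seed: int = 0
    # traces
    n_larvae_per_group: int = 24
    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    baseline_dark_mean: float = 1.2  # cm per 6-s bin
    baseline_light_mean: float = 0.4
    noise_cv: float = 0.25
    outlier_rate: float = 0.0  # per bin
    outlier_scale: float = 6.0
    nonresponder_rate: float = 0.0  # per larva
    nonresponder_light_factor: float = 1.2  # light mean as multiple of dark mean
    # screening
    n_embryos_per_condition: int = 150
    # DE tables
    n_genes: int = 5000
    n_true_deg: int = 50
    lfc_effect_mean: float = 1.5
    lfc_effect_sd: float = 0.3
    lfc_effect_min: float = 0.0  # lower truncation of planted |log2FC|
    null_lfc_sd: float = 0.2
    planted_p_max: float = 1e-5
    shared_deg_counts: Mapping[frozenset, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "nonresponder_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_larvae_per_group", "n_embryos_per_condition", "n_genes", "n_true_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_true_deg > self.n_genes:
            raise ConfigurationError("n_true_deg cannot exceed n_genes")
        for name in ("baseline_dark_mean", "baseline_light_mean"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and non-negative")
        for g in self.groups:
            for m in (g.effect_multiplier_dark, g.effect_multiplier_light):
                if not np.isfinite(m) or m < 0:
                    raise ConfigurationError(
                        f"group {g.label}: effect multipliers must be finite and ≥ 0"
                    )
        if not 0 < self.planted_p_max <= 1:
            raise ConfigurationError("planted_p_max must be in (0, 1]")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(salt)])


# ---------------------------------------------------------------------------
# locomotion traces


@dataclass
class TraceTruth:
    """Ground-truth labels emitted alongside simulated traces."""

    nonresponders: set[str] = field(default_factory=set)
    outlier_bins: dict[str, list[int]] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)


def simulate_traces(
    config: SimulationConfig,
    schedule: PhotoperiodSchedule | None = None,
) -> tuple[list[LocomotionTrace], TraceTruth]:
    """Draw one trace per larva per group, plus ground-truth labels.

    Dark bins ~ N(baseline_dark × group multiplier, (cv·mean)²) clipped at 0,
    light bins analogously. Planted non-responders have their light mean
    rescaled to ``nonresponder_light_factor`` × their dark mean so the ratio
    rule removes them by construction. Planted outlier bins are multiplied
    by ``outlier_scale``.
    """
    schedule = schedule or PhotoperiodSchedule()
    if schedule.n_bins <= 0:
        raise ConfigurationError("schedule must contain at least one bin")
    rng = config.rng(_TRACE_SALT)
    phases = schedule.phase_labels()
    light_mask = phases == LIGHT
    traces: list[LocomotionTrace] = []
    truth = TraceTruth()
    for group in config.groups:
        dark_mean = config.baseline_dark_mean * group.effect_multiplier_dark
        light_mean = config.baseline_light_mean * group.effect_multiplier_light
        for i in range(config.n_larvae_per_group):
            larva_id = f"{group.label}/larva{i:03d}"
            is_nonresponder = rng.random() < config.nonresponder_rate
            lmean = (
                config.nonresponder_light_factor * dark_mean
                if is_nonresponder
                else light_mean
            )
            means = np.where(light_mask, lmean, dark_mean)
            sd = config.noise_cv * means
            values = np.clip(rng.normal(means, sd), 0.0, None)
            outliers = np.flatnonzero(rng.random(schedule.n_bins) < config.outlier_rate)
            values[outliers] *= config.outlier_scale
            traces.append(LocomotionTrace(larva_id, group.label, values, schedule))
            truth.group_of[larva_id] = group.label
            if is_nonresponder:
                truth.nonresponders.add(larva_id)
            if outliers.size:
                truth.outlier_bins[larva_id] = outliers.tolist()
    return traces, truth


# ---------------------------------------------------------------------------
# abnormality / mortality screening


def simulate_screening(
    config: SimulationConfig,
    baseline_probs: Mapping[str, float] | None = None,
    odds_ratios: Mapping[str, Mapping[str, float] | float] | None = None,
    mortality_per_interval: Mapping[str, float] | None = None,
    timepoints_hpf: Sequence[int] = TIMEPOINTS_HPF,
) -> pd.DataFrame:
    """Draw a screening count table (endpoint × condition × timepoint).

    Per larva: a static Bernoulli state per abnormality endpoint with
    ``logit(p) = logit(baseline) + log(OR)``, and a death time from a
    constant per-interval hazard. Mortality is cumulative among all embryos;
    abnormality endpoints are counted among survivors at each timepoint;
    ``total_abnormalities`` is any-morphological-abnormality per survivor.
    """
    baseline_probs = dict(baseline_probs or {})
    defaults = {"unhatched": 0.10, **{e: 0.04 for e in MORPH_ENDPOINTS}}
    for endpoint, p in defaults.items():
        baseline_probs.setdefault(endpoint, p)
    for endpoint, p in baseline_probs.items():
        if not 0 <= p <= 1:
            raise ConfigurationError(f"baseline probability for {endpoint} outside [0,1]: {p}")

    rng = config.rng(_SCREEN_SALT)
    n = config.n_embryos_per_condition
    binary_endpoints = ("unhatched",) + MORPH_ENDPOINTS
    rows = []
    for group in config.groups:
        or_map = _group_odds_ratios(odds_ratios, group.label, binary_endpoints)
        p_death = float((mortality_per_interval or {}).get(group.label, 0.01))
        if not 0 <= p_death <= 1:
            raise ConfigurationError(f"mortality probability outside [0,1]: {p_death}")
        states = {}
        for endpoint in binary_endpoints:
            p = _apply_odds_ratio(baseline_probs[endpoint], or_map[endpoint])
            states[endpoint] = rng.random(n) < p
        any_morph = np.logical_or.reduce([states[e] for e in MORPH_ENDPOINTS])
        # death interval per larva: geometric over the screening intervals
        dead_by = np.full(n, np.inf)
        alive = np.ones(n, dtype=bool)
        for t_i, t in enumerate(timepoints_hpf):
            dies = alive & (rng.random(n) < p_death)
            dead_by[dies] = t_i
            alive &= ~dies
            survivors = dead_by > t_i
            n_survivors = int(survivors.sum())
            counts = {"mortality": (int((~survivors).sum()), n)}
            for endpoint in binary_endpoints:
                counts[endpoint] = (int(states[endpoint][survivors].sum()), n_survivors)
            counts["total_abnormalities"] = (int(any_morph[survivors].sum()), n_survivors)
            for endpoint, (affected, total) in counts.items():
                rows.append(
                    {
                        "endpoint": endpoint,
                        "chemical": group.chemical,
                        "concentration_nM": group.concentration_nM,
                        "duration": group.duration,
                        "timepoint_hpf": t,
                        "n_affected": affected,
                        "n_total": total,
                    }
                )
    return pd.DataFrame(rows)


def _group_odds_ratios(odds_ratios, label, endpoints) -> dict[str, float]:
    spec = (odds_ratios or {}).get(label, 1.0)
    if isinstance(spec, Mapping):
        return {e: float(spec.get(e, 1.0)) for e in endpoints}
    return {e: float(spec) for e in endpoints}


def _apply_odds_ratio(p: float, odds_ratio: float) -> float:
    if odds_ratio < 0:
        raise ConfigurationError("odds ratio must be non-negative")
    if p in (0.0, 1.0):
        return p
    odds = p / (1 - p) * odds_ratio
    return odds / (1 + odds)


# ---------------------------------------------------------------------------
# differential-expression tables


@dataclass
class DEGTruth:
    """Planted-gene labels: per condition and per shared chemical set."""

    planted_by_condition: dict[str, set[str]] = field(default_factory=dict)
    shared_genes: dict[frozenset, list[str]] = field(default_factory=dict)

    def planted_by_chemical(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for label, genes in self.planted_by_condition.items():
            chemical = label.split(":", 1)[0]
            out.setdefault(chemical, set()).update(genes)
        return out


def simulate_deg_table(config: SimulationConfig) -> tuple[pd.DataFrame, DEGTruth]:
    """Draw per-gene DE results for every non-control condition.

    Null genes: log2FC ~ N(0, null_lfc_sd), raw p ~ U(0,1). Planted genes:
    |log2FC| ~ N(lfc_effect_mean, lfc_effect_sd) truncated at lfc_effect_min
    with random sign, raw p ~ U(0, planted_p_max). Genes listed in
    ``shared_deg_counts`` are planted in the first condition of every member
    chemical (and nowhere else), so a chemical's combined significant set
    contains them exactly for the member chemicals. Adjusted p is
    Benjamini–Hochberg within each condition.
    """
    conditions = [g for g in config.groups if not g.is_control]
    if not conditions:
        raise ConfigurationError("no non-control conditions to simulate")
    rng = config.rng(_DEG_SALT)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])
    chemicals = list(dict.fromkeys(g.chemical for g in conditions))
    first_condition = {
        chem: next(g.label for g in conditions if g.chemical == chem) for chem in chemicals
    }

    truth = DEGTruth(planted_by_condition={g.label: set() for g in conditions})
    next_gene = 0

    for chem_set, count in config.shared_deg_counts.items():
        members = frozenset(chem_set)
        if count < 0:
            raise ConfigurationError("shared_deg_counts must be non-negative")
        unknown = members - set(chemicals)
        if unknown:
            raise ConfigurationError(f"shared_deg_counts names unknown chemicals: {sorted(unknown)}")
        if next_gene + count > config.n_genes:
            raise ConfigurationError("shared_deg_counts exceed n_genes")
        allocated = list(genes[next_gene : next_gene + count])
        next_gene += count
        truth.shared_genes[members] = allocated
        for chem in members:
            truth.planted_by_condition[first_condition[chem]].update(allocated)

    for g in conditions:
        planted = truth.planted_by_condition[g.label]
        if len(planted) > config.n_true_deg:
            raise ConfigurationError(
                f"condition {g.label}: shared plants ({len(planted)}) exceed n_true_deg"
            )
        n_fill = config.n_true_deg - len(planted)
        if next_gene + n_fill > config.n_genes:
            raise ConfigurationError("n_true_deg plants exceed n_genes")
        planted.update(genes[next_gene : next_gene + n_fill])
        next_gene += n_fill

    frames = []
    for g in conditions:
        lfc = rng.normal(0.0, config.null_lfc_sd, size=config.n_genes)
        raw_p = rng.uniform(size=config.n_genes)
        planted_mask = np.isin(genes, list(truth.planted_by_condition[g.label]))
        n_planted = int(planted_mask.sum())
        if n_planted:
            magnitude = np.maximum(
                rng.normal(config.lfc_effect_mean, config.lfc_effect_sd, size=n_planted),
                config.lfc_effect_min,
            )
            sign = rng.choice([-1.0, 1.0], size=n_planted)
            lfc[planted_mask] = sign * magnitude
            raw_p[planted_mask] = rng.uniform(0.0, config.planted_p_max, size=n_planted)
        padj = bh_adjust(raw_p)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "chemical": g.chemical,
                    "concentration_nM": g.concentration_nM,
                    "duration": g.duration,
                    "log2fc": lfc,
                    "padj": padj,
                    "raw_p": raw_p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), truth


def bh_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        return raw_p.copy()
    return multipletests(raw_p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sidecar I/O


def write_truth_json(path, trace_truth: TraceTruth | None = None, deg_truth: DEGTruth | None = None):
    import json
    from pathlib import Path

    payload: dict = {}
    if trace_truth is not None:
        payload["traces"] = {
            "nonresponders": sorted(trace_truth.nonresponders),
            "outlier_bins": trace_truth.outlier_bins,
            "group_of": trace_truth.group_of,
        }
    if deg_truth is not None:
        payload["deg"] = {
            "planted_by_condition": {
                k: sorted(v) for k, v in deg_truth.planted_by_condition.items()
            },
            "shared_genes": {
                "+".join(sorted(k)): v for k, v in deg_truth.shared_genes.items()
            },
        }
    Path(path).write_text(json.dumps(payload, indent=2))
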