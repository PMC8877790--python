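"""DEG significance filtering and count/overlap accounting.

A gene is called differentially expressed in a condition when
``|log2FC| ≥ 0.75`` (inclusive) **and** ``padj < 0.1`` (strict); a missing
adjusted p (NA from upstream independent filtering) is never significant and
is tallied separately as "untested".

Two duration-total bookkeeping policies are supported because published DEG
tables commonly mix them:

* ``"sum"`` — add the per-concentration counts; a gene significant at two
  concentrations counts twice.
* ``"unique"`` — each gene counts once per (chemical, duration); genes
  significant in opposite directions at different concentrations are
  reported as *variably regulated*.

Set overlaps (Venn regions) are computed exactly for up to 5 named sets,
with "combined" per-chemical sets built by unioning a chemical's significant
genes over all concentrations and durations before intersecting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DEG_COLUMNS = ["gene_id", "chemical", "concentration_nM", "duration", "log2fc", "padj"]
LFC_CUT = 0.75
PADJ_CUT = 0.1
CONDITION_KEYS = ["chemical", "duration"]


def validate_deg_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(DEG_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")
    padj = records["padj"]
    bad = padj.notna() & ((padj < 0) | (padj > 1))
    if bad.any():
        raise ValidationError("padj values must lie in [0, 1] (or be missing)")
    if not np.isfinite(records["log2fc"]).all():
        raise ValidationError("log2fc values must be finite")
    return records


def filter_degs(
    records: pd.DataFrame,
    lfc_cut: float = LFC_CUT,
    padj_cut: float = PADJ_CUT,
) -> pd.DataFrame:
    """Apply the significance filter; adds a ``direction`` column (up/down).

    Keeps rows with ``|log2fc| ≥ lfc_cut`` and ``padj < padj_cut``. The
    returned frame carries ``.attrs["n_untested"]``: rows with missing padj.
    """
    if lfc_cut <= 0 or padj_cut <= 0:
        raise ValidationError("thresholds must be strictly positive")
    validate_deg_table(records)
    untested = records["padj"].isna()
    keep = (records["log2fc"].abs() >= lfc_cut) & (records["padj"] < padj_cut) & ~untested
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.attrs["n_untested"] = int(untested.sum())
    return out


@dataclass
class DEGCounts:
    """Per-concentration and per-duration DEG tallies."""

    per_concentration: pd.DataFrame  # chemical, duration, concentration_nM, n_up, n_down
    per_duration: pd.DataFrame  # chemical, duration, total_up, total_down, total,
    #                             n_unique, n_variably_regulated
    dedup_policy: str


def count_by_condition(significant: pd.DataFrame, dedup_policy: str = "sum") -> DEGCounts:
    """Tally filtered records per concentration and per duration.

    Under ``"sum"`` the duration total adds the per-concentration counts;
    under ``"unique"`` it is the number of distinct genes, with opposite-sign
    genes reported in ``n_variably_regulated``. ``n_unique`` and
    ``n_variably_regulated`` are reported under both policies.
    """
    if dedup_policy not in ("sum", "unique"):
        raise ValidationError(f"unknown dedup policy {dedup_policy!r}")
    needed = set(DEG_COLUMNS) - {"padj"} | {"direction"}
    missing = needed - set(significant.columns)
    if missing:
        raise ValidationError(f"significant records missing columns: {sorted(missing)}")

    per_conc = (
        significant.groupby(
            ["chemical", "duration", "concentration_nM"], sort=True, as_index=False
        )
        .agg(
            n_up=("direction", lambda d: int((d == "up").sum())),
            n_down=("direction", lambda d: int((d == "down").sum())),
        )
    )

    rows = []
    for (chem, dur), sub in significant.groupby(CONDITION_KEYS, sort=True):
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        directions = sub.groupby("gene_id")["direction"].agg(set)
        n_unique = len(directions)
        n_variable = int((directions.map(len) > 1).sum())
        total = n_up + n_down if dedup_policy == "sum" else n_unique
        rows.append(
            {
                "chemical": chem,
                "duration": dur,
                "total_up": n_up,
                "total_down": n_down,
                "total": total,
                "n_unique": n_unique,
                "n_variably_regulated": n_variable,
            }
        )
    per_duration = pd.DataFrame(
        rows,
        columns=[
            "chemical",
            "duration",
            "total_up",
            "total_down",
            "total",
            "n_unique",
            "n_variably_regulated",
        ],
    )
    return DEGCounts(per_conc, per_duration, dedup_policy)


@dataclass
class OverlapResult:
    """Exact Venn decomposition of ≥ 2 named gene sets."""

    set_names: tuple[str, ...]
    region_counts: dict[frozenset, int]
    region_genes: dict[frozenset, set]

    def count(self, *names: str) -> int:
        """Count of the region containing exactly these sets (and no others)."""
        return self.region_counts.get(frozenset(names), 0)

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_json_dict(self) -> dict:
        return {
            "sets": list(self.set_names),
            "regions": [
                {
                    "members": sorted(region),
                    "count": count,
                    "genes": sorted(self.region_genes[region]),
                }
                for region, count in sorted(
                    self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                )
            ],
        }


def overlap_sets(named_sets: Mapping[str, set]) -> OverlapResult:
    """Decompose named gene sets into disjoint Venn regions (up to 5 sets)."""
    names = list(named_sets)
    if len(names) < 2:
        raise ValidationError("need at least 2 named sets")
    if len(names) > 5:
        raise ValidationError("exact Venn decomposition supported for up to 5 sets")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate set names")
    sets = {name: set(named_sets[name]) for name in names}
    region_genes: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(set(), *(sets[m] for m in names if m not in members))
            region_genes[frozenset(members)] = inside - outside
    counts = {region: len(genes) for region, genes in region_genes.items()}
    return OverlapResult(tuple(names), counts, region_genes)


def combined_chemical_sets(significant: pd.DataFrame) -> dict[str, set]:
    """Per-chemical significant gene sets, unioned over concentrations and
    durations (the construction behind a combined-exposure Venn diagram)."""
    return {
        str(chem): set(sub["gene_id"])
        for chem, sub in significant.groupby("chemical", sort=True)
    }


def annotate_categories(
    significant: pd.DataFrame,
    category_map: Mapping[str, str] | str | Path,
    dedup_policy: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-join gene → functional category labels onto filtered records.

    ``category_map`` is a mapping or a two-column TSV (gene_id, category).
    Unmapped genes are labeled "unassigned". Returns (annotated records,
    per-category counts per chemical × duration); under "unique" a gene
    counts once per condition regardless of how many concentrations hit it.
    """
    if dedup_policy not in ("sum", "unique"):
        raise ValidationError(f"unknown dedup policy {dedup_policy!r}")
    if not isinstance(category_map, Mapping):
        mapping = _read_category_tsv(category_map)
    else:
        mapping = dict(category_map)
    annotated = significant.copy()
    annotated["category"] = annotated["gene_id"].map(mapping).fillna("unassigned")
    if dedup_policy == "unique":
        deduped = annotated.drop_duplicates(subset=["gene_id", *CONDITION_KEYS])
    else:
        deduped = annotated
    counts = (
        deduped.groupby([*CONDITION_KEYS, "category"], sort=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return annotated, counts


def _read_category_tsv(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"category map line {i + 1}: expected 2 tab-separated fields")
        if i == 0 and parts[0].lower() in ("gene_id", "gene"):
            continue
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_deg_tables(
    path: str | Path,
    dialect: str = "tidy",
    condition: tuple[str, float, str] | None = None,
) -> pd.DataFrame:
    """Read DE results.

    ``dialect="tidy"`` expects the package's TSV schema (gene_id, chemical,
    concentration_nM, duration, log2fc, padj[, raw_p]). ``dialect="deseq2"``
    reads a one-condition results-style TSV (gene id in the first column,
    log2FoldChange, padj) and requires ``condition=(chemical,
    concentration_nM, duration)``.
    """
    path = Path(path)
    if dialect == "tidy":
        df = pd.read_csv(path, sep="\t")
        return validate_deg_table(df)
    if dialect == "deseq2":
        if condition is None:
            raise ValidationError("deseq2 dialect requires a condition label")
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        if "log2foldchange" not in cols or "padj" not in cols:
            raise ValidationError("deseq2 table needs log2FoldChange and padj columns")
        chem, conc, dur = condition
        out = pd.DataFrame(
            {
                "gene_id": df.iloc[:, 0].astype(str),
                "chemical": chem,
                "concentration_nM": float(conc),
                "duration": dur,
                "log2fc": df[cols["log2foldchange"]].astype(float),
                "padj": df[cols["padj"]].astype(float),
            }
        )
        return validate_deg_table(out)
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_deg_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)
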