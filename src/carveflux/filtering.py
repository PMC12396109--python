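"""Expression filtering: from a UMI count table to condition-specific expressed-gene lists.

Carving consumes only the *identity* of expressed genes, so the expression
threshold is the single most influential upstream choice.  The default rule
mirrors the widely used count-based filter from differential-expression
practice: a gene is kept for a condition when it reaches a CPM cutoff
(derived from ``min_count`` and the condition's median library size) in a
sufficient fraction of that condition's samples, and its total count over
the condition clears ``min_total_count``.  Two simpler alternatives (raw
count, fixed CPM) are selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterParams",
    "compute_cpm",
    "filter_expressed",
    "read_counts_tsv",
    "read_design_tsv",
    "write_gene_list",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts plus a sample -> condition design."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    design: pd.Series  # index: sample ids, values: condition labels

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral (UMI counts)")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def conditions(self) -> list[str]:
        return sorted(self.design.unique())

    def samples_of(self, condition: str) -> list[str]:
        if condition not in set(self.design):
            raise KeyError(
                f"unknown condition {condition!r}; available: {self.conditions()}"
            )
        return [s for s in self.sample_ids if self.design[s] == condition]


@dataclass
class FilterParams:
    """Expression-filter parameters (defaults follow the recommended count filter).

    method "recommended": CPM cutoff = min_count / median(library sizes) * 1e6,
    required in >= ceil(min_prop * n_samples) samples of the condition, plus a
    min_total_count on the condition's summed counts.
    method "raw": count >= min_count in >= min_samples samples.
    method "cpm": CPM >= cpm_cutoff in >= min_samples samples.
    """

    min_count: float = 10.0
    min_total_count: float = 15.0
    min_prop: float = 0.7
    method: str = "recommended"
    min_samples: int = 1
    cpm_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_count, self.min_total_count, self.cpm_cutoff) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.min_prop <= 1:
            raise ValueError("min_prop must lie in (0, 1]")
        if self.method not in ("recommended", "raw", "cpm"):
            raise ValueError(f"unknown filter method {self.method!r}")


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled by 1e6 / its library size (column sum)."""
    libs = counts.sum(axis=0)
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / libs * 1e6


def filter_expressed(
    expr: ExpressionMatrix, condition: str, params: FilterParams | None = None
) -> list[str]:
    """Expressed-gene list for one condition (sorted, deduplicated)."""
    params = params or FilterParams()
    samples = expr.samples_of(condition)
    sub = expr.counts[samples]
    if params.method == "recommended":
        libs = sub.sum(axis=0)
        cutoff = params.min_count / float(np.median(libs)) * 1e6
        n_kept = math.ceil(params.min_prop * len(samples))
        cpm = compute_cpm(sub)
        keep = ((cpm >= cutoff).sum(axis=1) >= n_kept) & (
            sub.sum(axis=1) >= params.min_total_count
        )
    elif params.method == "raw":
        keep = (sub >= params.min_count).sum(axis=1) >= params.min_samples
    else:  # cpm
        cpm = compute_cpm(sub)
        keep = (cpm >= params.cpm_cutoff).sum(axis=1) >= params.min_samples
    keep &= sub.sum(axis=1) > 0  # a gene never observed cannot be expressed
    return sorted(sub.index[keep])


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """TSV count table: first column gene id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_design_tsv(path: str | Path) -> pd.Series:
    """TSV design table with columns ``sample`` and ``condition``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"design table lacks required column {col!r}")
    return pd.Series(df["condition"].values, index=df["sample"].values)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
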