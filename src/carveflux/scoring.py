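"""Reaction-level scoring of a sampled solution space.

Two complementary per-reaction summaries are computed from a flux sample
matrix:

* the **reaction cumulative correlation** (RCC): the sum over all reactions
  of the absolute pairwise flux correlation with the given reaction,
  self-term included.  RCC ranges from 0 (a constant-flux reaction, by the
  zero-variance convention) to the model's reaction count (a reaction
  perfectly correlated with every other); it is a weighted-centrality-like
  essentiality measure — perturbing a high-RCC reaction propagates to the
  whole network;
* the **mean flux** (usage, mol·kgDW⁻¹·h⁻¹) and its standard deviation.

Between two conditions, mean-flux differences are tested per reaction with
Welch's unequal-variance comparison on strided (decorrelated) samples;
reactions carved out of one condition count as carrying zero flux there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sampling import FluxSampleMatrix

__all__ = [
    "correlation_matrix",
    "rcc_scores",
    "mean_fluxes",
    "reaction_score_table",
    "differential_reactions",
    "rcc_histogram",
    "rank_by_rcc",
]


def correlation_matrix(samples: FluxSampleMatrix, method: str = "pearson") -> pd.DataFrame:
    """Pairwise flux correlation matrix (reactions x reactions).

    Zero-variance convention: a constant flux column has correlation 0
    against every column *including itself*, so its RCC is exactly 0 and
    the RCC range endpoints [0, N] are attainable.
    """
    if samples.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlations, got {samples.n_samples}")
    V = samples.values
    if method == "spearman":
        V = np.apply_along_axis(stats.rankdata, 0, V)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = V.std(axis=0)
    const = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, np.where(const, 0.0, 1.0))
    np.clip(corr, -1.0, 1.0, out=corr)
    return pd.DataFrame(corr, index=samples.reaction_ids, columns=samples.reaction_ids)


def rcc_scores(corr: pd.DataFrame) -> pd.Series:
    """RCC per reaction: sum of absolute pairwise correlations (self included)."""
    return corr.abs().sum(axis=1)


def mean_fluxes(samples: FluxSampleMatrix) -> pd.DataFrame:
    """Arithmetic mean and sample standard deviation per reaction column."""
    V = samples.values
    sd = V.std(axis=0, ddof=1) if samples.n_samples > 1 else np.zeros(V.shape[1])
    return pd.DataFrame(
        {"mean_flux": V.mean(axis=0), "flux_sd": sd}, index=samples.reaction_ids
    )


def reaction_score_table(
    samples: FluxSampleMatrix, correlation: str = "pearson"
) -> pd.DataFrame:
    """Per-reaction score table: rcc, mean_flux, flux_sd, n_samples."""
    out = mean_fluxes(samples)
    out.insert(0, "rcc", rcc_scores(correlation_matrix(samples, method=correlation)))
    out["n_samples"] = samples.n_samples
    out.index.name = "reaction_id"
    return out


def _stride(n: int, cap: int = 1000) -> int:
    return max(1, math.ceil(n / cap))


def _one_sided_vs_zero(x: np.ndarray) -> float:
    """P-value convention for a reaction absent from the other condition.

    The absent side is an identically-zero flux column.  A zero-variance
    present column gives p = 1 if it is also zero, else 0; otherwise p = 0
    when the mean is more than one standard error from zero, else a
    one-sample comparison against 0.
    """
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0:
        return 1.0 if mean == 0.0 else 0.0
    if abs(mean) > sd / math.sqrt(len(x)):
        return 0.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def _welch(xa: np.ndarray, xb: np.ndarray) -> float:
    sa, sb = xa.std(ddof=1), xb.std(ddof=1)
    if sa == 0.0 and sb == 0.0:
        return 1.0 if xa.mean() == xb.mean() else 0.0
    p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def differential_reactions(
    a: tuple[pd.DataFrame, FluxSampleMatrix],
    b: tuple[pd.DataFrame, FluxSampleMatrix],
    test_stride: int | None = None,
) -> pd.DataFrame:
    """Differential reaction table over the union of two carved models.

    delta_mean_flux and delta_rcc are condition A minus condition B, with
    the absent side contributing zero; p_value is a two-sided Welch test on
    every ``test_stride``-th sample (default: at most 1000 per side, to
    blunt sampler autocorrelation).
    """
    table_a, samples_a = a
    table_b, samples_b = b
    set_a, set_b = set(table_a.index), set(table_b.index)
    if not set_a & set_b:
        raise ValueError(
            "reaction namespaces are disjoint; were these models carved "
            "from the same universal model?"
        )
    rows = []
    for rxn in sorted(set_a | set_b):
        in_a, in_b = rxn in set_a, rxn in set_b
        mean_a = table_a.at[rxn, "mean_flux"] if in_a else 0.0
        mean_b = table_b.at[rxn, "mean_flux"] if in_b else 0.0
        rcc_a = table_a.at[rxn, "rcc"] if in_a else 0.0
        rcc_b = table_b.at[rxn, "rcc"] if in_b else 0.0
        if in_a:
            xa = samples_a.column(rxn)
            xa = xa[:: test_stride or _stride(len(xa))]
        if in_b:
            xb = samples_b.column(rxn)
            xb = xb[:: test_stride or _stride(len(xb))]
        if in_a and in_b:
            p = _welch(xa, xb)
        else:
            p = _one_sided_vs_zero(xa if in_a else xb)
        rows.append(
            {
                "reaction_id": rxn,
                "delta_mean_flux": mean_a - mean_b,
                "p_value": p,
                "delta_rcc": rcc_a - rcc_b,
                "in_model_a": in_a,
                "in_model_b": in_b,
            }
        )
    return pd.DataFrame(rows).set_index("reaction_id")


def rcc_histogram(rcc: pd.Series, bins: int = 50) -> pd.DataFrame:
    """Histogram of the RCC distribution as a plot-ready table."""
    values = rcc.to_numpy()
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:  # all reactions equally central: one degenerate bin
        lo, hi, bins = lo - 0.5, hi + 0.5, 1
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def rank_by_rcc(table: pd.DataFrame) -> pd.DataFrame:
    """Reactions ranked by descending RCC (rank 1 = most central)."""
    out = table.sort_values("rcc", ascending=False).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out
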