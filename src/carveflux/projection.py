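"""Projection of reaction-level scores onto genes through GPR membership.

A gene is "involved" in every reaction whose GPR rule mentions it (isozyme
vs. complex semantics do not alter membership).  Scores are aggregated over
a gene's reactions — by default the value largest in magnitude, signed
(a gene is as metabolically important as its most important reaction) —
and condition-signature genes are selected by thresholds on the projected
differential flux usage and its significance.
"""

from __future__ import annotations

import cobra
import pandas as pd

from .gpr import parse_gpr

__all__ = [
    "gene_reaction_map",
    "project_scores",
    "gene_reaction_long_table",
    "select_signature_genes",
]


def gene_reaction_map(model: cobra.Model) -> dict[str, set[str]]:
    """Gene -> set of reaction ids whose GPR tree contains the gene."""
    mapping: dict[str, set[str]] = {}
    for rxn in model.reactions:
        expr = parse_gpr(rxn.gene_reaction_rule)
        if expr is None:
            continue
        for g in expr.genes():
            mapping.setdefault(g, set()).add(rxn.id)
    return mapping


def _aggregate(values: pd.Series, aggregation: str) -> float:
    if aggregation == "max":
        return float(values.loc[values.abs().idxmax()])  # max |v|, sign kept
    if aggregation == "mean":
        return float(values.mean())
    if aggregation == "sum":
        return float(values.sum())
    raise ValueError(f"unknown aggregation {aggregation!r}; use max, mean or sum")


def project_scores(
    scores: pd.DataFrame,
    mapping: dict[str, set[str]],
    aggregation: str = "max",
) -> pd.DataFrame:
    """Project a reaction score table (plain or differential) onto genes.

    Plain tables (columns rcc, mean_flux) yield per-gene ``rcc_gene`` and
    ``usage_gene``; differential tables (delta_mean_flux, p_value,
    delta_rcc) yield ``delta_usage_gene``, ``delta_rcc_gene``, the
    ``best_reaction`` attaining the largest |delta_mean_flux| and that
    reaction's ``p_value``.  Genes whose reactions all fall outside the
    table are omitted.
    """
    if not mapping:
        raise ValueError("empty gene->reaction mapping")
    differential = "delta_mean_flux" in scores.columns
    rows = []
    for gene in sorted(mapping):
        rxns = sorted(mapping[gene] & set(scores.index))
        if not rxns:
            continue
        sub = scores.loc[rxns]
        row: dict = {"gene": gene, "n_reactions": len(rxns), "reaction_ids": ";".join(rxns)}
        if differential:
            row["delta_usage_gene"] = _aggregate(sub["delta_mean_flux"], aggregation)
            row["delta_rcc_gene"] = _aggregate(sub["delta_rcc"], aggregation)
            best = sub["delta_mean_flux"].abs().idxmax()
            row["best_reaction"] = best
            row["p_value"] = float(sub.at[best, "p_value"])
        else:
            row["rcc_gene"] = _aggregate(sub["rcc"], aggregation)
            row["usage_gene"] = _aggregate(sub["mean_flux"], aggregation)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def gene_reaction_long_table(scores: pd.DataFrame, mapping: dict[str, set[str]]) -> pd.DataFrame:
    """Full gene x reaction long table (no aggregation, nothing lost)."""
    rows = []
    for gene in sorted(mapping):
        for rxn in sorted(mapping[gene] & set(scores.index)):
            row = {"gene": gene, "reaction_id": rxn}
            row.update(scores.loc[rxn].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def select_signature_genes(
    diff: pd.DataFrame,
    delta_threshold: float = 0.5,
    p_threshold: float = 0.05,
    direction: str = "a_over_b",
) -> list[str]:
    """Condition-signature genes from a differential gene score table.

    ``a_over_b`` keeps genes whose projected flux-usage difference exceeds
    ``+delta_threshold`` with ``p_value < p_threshold``; ``b_over_a`` keeps
    those below ``-delta_threshold``.  Defaults (0.5 flux units, p < .05)
    follow common practice for flux-difference signatures.
    """
    if direction == "a_over_b":
        keep = diff["delta_usage_gene"] > delta_threshold
    elif direction == "b_over_a":
        keep = diff["delta_usage_gene"] < -delta_threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    keep &= diff["p_value"] < p_threshold
    return sorted(diff.index[keep])
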