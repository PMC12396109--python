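"""Gene-set enrichment of metabolically scored genes.

Over-representation analysis (ORA) tests a selected gene list against named
gene sets with the upper-tail hypergeometric distribution; pre-ranked GSEA
runs the weighted Kolmogorov-Smirnov running sum over genes ranked by their
differential metabolic score, with a gene-permutation null.  The universe
for ORA defaults to the carved model's gene set — drawing the signature from
model genes and testing against the whole genome would inflate enrichment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "write_gmt", "ora", "gsea_preranked"]

logger = logging.getLogger(__name__)

GeneSetCollection = dict[str, tuple[str, frozenset[str]]]  # name -> (description, members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT format: one set per line, tab-separated name, description, members."""
    collection: GeneSetCollection = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
        name, desc, members = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
        if name in collection:
            raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
        if not members:
            raise ValueError(f"{path}:{ln}: empty gene set {name!r}")
        collection[name] = (desc, members)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *sorted(members)])
        for name, (desc, members) in collection.items()
    ]
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def ora(
    selected: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation analysis by the upper-tail hypergeometric test.

    Per set: ``P(X >= overlap)`` with population = |universe|, successes =
    |set ∩ universe| and draws = |selected|; Benjamini-Hochberg adjustment
    across all tested sets; rows sorted by p_value.
    """
    selected, universe = frozenset(selected), frozenset(universe)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:10]}")
    rows = []
    for name, (desc, members) in collection.items():
        in_universe = members & universe
        overlap = in_universe & selected
        p = float(hypergeom.sf(len(overlap) - 1, len(universe), len(in_universe), len(selected)))
        rows.append(
            {
                "set_name": name,
                "description": desc,
                "overlap": len(overlap),
                "set_size": len(in_universe),
                "universe_size": len(universe),
                "selected_size": len(selected),
                "p_value": min(p, 1.0),
                "overlap_genes": ";".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def _running_sum_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Enrichment score: extremum of the weighted KS running sum."""
    n = len(in_set)
    n_hit = int(in_set.sum())
    hit_total = weights[in_set].sum()
    if hit_total == 0:  # all-zero scores: every hit steps equally
        hit_step = np.where(in_set, 1.0 / n_hit, 0.0)
    else:
        hit_step = np.where(in_set, weights / hit_total, 0.0)
    miss_step = np.where(in_set, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(hit_step - miss_step)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Pre-ranked GSEA on a gene -> score series (e.g. delta metabolic scores).

    Genes are sorted by descending score (ties broken by gene id); the
    running sum increments by |score|**weight within the set and decrements
    uniformly outside.  The null is ``n_perm`` seeded permutations of set
    membership; NES = ES / mean(|null ES| of matching sign) and the
    empirical permutation p carries a +1 pseudocount.  Sets with fewer than
    2 members in the ranked list are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    scores = ranked.loc[order].to_numpy(dtype=float)
    weights = np.abs(scores) ** weight
    genes = pd.Index(order)
    rng = np.random.default_rng(seed)

    rows = []
    for name, (desc, members) in collection.items():
        in_set = np.asarray(genes.isin(members))
        n_hit = int(in_set.sum())
        if n_hit < 2:
            logger.warning("set %r has < 2 members in the ranked list; skipped", name)
            continue
        es = _running_sum_es(in_set, weights)
        null = np.empty(n_perm)
        for k in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=n_hit, replace=False)] = True
            null[k] = _running_sum_es(perm, weights)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + len(same_sign))
        rows.append(
            {
                "set_name": name,
                "description": desc,
                "set_size": n_hit,
                "es": es,
                "nes": float(nes),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
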