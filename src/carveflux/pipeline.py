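"""End-to-end pipeline orchestration with a single reproducible configuration.

A run walks filter -> carve -> sample -> score per condition, then the
differential/projection/enrichment/reporting stages per requested condition
pair.  All stage outputs are persisted under the output directory; sampling
(the expensive stage) is resumable from its persisted matrix.  All
randomness derives from the single top-level seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import carve as carve_mod
from . import enrichment as enrich_mod
from . import projection, reporting, sampling, scoring
from .filtering import (
    ExpressionMatrix,
    FilterParams,
    filter_expressed,
    read_counts_tsv,
    read_design_tsv,
    write_gene_list,
)
from .model_io import model_genes, read_model, write_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "apply_medium"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSection(_Strict):
    min_count: float = 10.0
    min_total_count: float = 15.0
    min_prop: float = 0.7
    method: str = "recommended"
    min_samples: int = 1
    cpm_cutoff: float = 1.0

    def to_params(self) -> FilterParams:
        return FilterParams(**self.model_dump())


class CarveSection(_Strict):
    f_min: float = 0.1
    penalty_absent: float = 1.0
    penalty_nogpr: float = 0.01
    flux_activation_eps: float = 1e-4
    solver_gap: float = 1e-6

    def to_config(self) -> carve_mod.CarveConfig:
        return carve_mod.CarveConfig(**self.model_dump())


class SamplerSection(_Strict):
    method: str = "global"  # "global" | "corner"
    thinning: int = 100
    batch_size: int = 5000
    max_samples: int = 150_000
    n_corner: int = 1000
    rl_q: float = 0.025
    rl_r: float = 0.005
    rl_s: float = 0.95

    def to_config(self, seed: int) -> sampling.SamplerConfig:
        return sampling.SamplerConfig(
            thinning=self.thinning,
            batch_size=self.batch_size,
            max_samples=self.max_samples,
            seed=seed,
            rl_q=self.rl_q,
            rl_r=self.rl_r,
            rl_s=self.rl_s,
        )


class RunConfig(_Strict):
    """Single-file configuration of a full run (unknown keys are rejected)."""

    model_path: str
    counts_path: str
    design_path: str
    outdir: str = "carveflux_run"
    de_table_path: Optional[str] = None
    medium_path: Optional[str] = None
    gmt_paths: list[str] = []
    biomass: Optional[str] = None
    conditions: Optional[list[str]] = None  # default: every condition in the design
    condition_pairs: list[tuple[str, str]] = []
    seed: int = 0
    aggregation: str = "max"
    correlation: str = "pearson"
    delta_threshold: float = 0.5
    p_threshold: float = 0.05
    fc_threshold: float = 1.0
    figures: bool = False
    filter: FilterSection = FilterSection()
    carve: CarveSection = CarveSection()
    sampler: SamplerSection = SamplerSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def apply_medium(model, path: str | Path) -> None:
    """Override exchange lower bounds from a TSV (columns reaction_id, lower_bound)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("reaction_id", "lower_bound"):
        if col not in df.columns:
            raise ValueError(f"medium table lacks required column {col!r}")
    for _, row in df.iterrows():
        model.reactions.get_by_id(str(row["reaction_id"])).lower_bound = float(
            row["lower_bound"]
        )


def _condition_seed(base: int, index: int) -> int:
    # deterministic, collision-free per condition, kept below 2**31
    return (base * 1_000_003 + 7919 * (index + 1)) % (2**31)


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Run every stage and return the report directory.

    With ``resume=True`` a condition whose persisted sample matrix already
    exists is not re-sampled.
    """
    t0 = time.time()
    out = Path(config.outdir)
    for sub in ("models", "samples", "scores", "enrichment", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    universal = read_model(config.model_path, biomass=config.biomass)
    if config.medium_path:
        apply_medium(universal, config.medium_path)
    counts = read_counts_tsv(config.counts_path)
    design = read_design_tsv(config.design_path)
    expr = ExpressionMatrix(counts=counts, design=design)
    conditions = config.conditions or expr.conditions()
    filt = config.filter.to_params()
    carve_cfg = config.carve.to_config()

    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "seed": config.seed,
        "conditions": conditions,
        "config": config.model_dump(),
        "stages": {},
    }

    per_condition: dict[str, dict] = {}
    for i, cond in enumerate(conditions):
        stage = {}
        expressed = filter_expressed(expr, cond, filt)
        write_gene_list(expressed, out / "scores" / f"expressed_{cond}.txt")
        stage["n_expressed"] = len(expressed)

        scores = carve_mod.score_reactions(universal, set(expressed), carve_cfg)
        carved = carve_mod.carve(universal, scores, carve_cfg)
        tables[f"models/carve_report_{cond}.tsv"] = carved.report.set_index("reaction_id")
        write_model(carved.model, out / "models" / f"{cond}.xml")
        write_model(carved.model, out / "models" / f"{cond}.json")
        stage["carve_objective"] = carved.objective_value
        stage["n_reactions_carved"] = len(carved.model.reactions)

        deblocked = carve_mod.remove_blocked(carved.model)
        seed = _condition_seed(config.seed, i)
        sample_path = out / "samples" / f"{cond}.tsv"
        if resume and sample_path.exists():
            samples = sampling.read_samples(sample_path)
            report = None
            stage["sampling"] = "resumed"
        elif config.sampler.method == "corner":
            samples = sampling.sample_corner(deblocked, config.sampler.n_corner, seed=seed)
            report = None
            sampling.write_samples(samples, sample_path)
        else:
            samples, report = sampling.sample_until_converged(
                deblocked, config.sampler.to_config(seed)
            )
            sampling.write_samples(samples, sample_path, report)
            stage["sampling"] = report.to_dict()

        score_table = scoring.reaction_score_table(samples, correlation=config.correlation)
        tables[f"scores/reactions_{cond}.tsv"] = score_table
        tables[f"report/rcc_histogram_{cond}.tsv"] = scoring.rcc_histogram(score_table["rcc"])
        tables[f"report/rcc_ranked_{cond}.tsv"] = scoring.rank_by_rcc(score_table)
        per_condition[cond] = {
            "model": carved.model,
            "samples": samples,
            "scores": score_table,
        }
        manifest["stages"][cond] = stage

    de = reporting.read_de_table(config.de_table_path) if config.de_table_path else None
    if de is None:
        manifest["volcano"] = "omitted (no DE table supplied)"

    pairs = [tuple(p) for p in config.condition_pairs]
    if not pairs and len(conditions) == 2:
        pairs = [(conditions[0], conditions[1])]
    for cond_a, cond_b in pairs:
        pa, pb = per_condition[cond_a], per_condition[cond_b]
        tag = f"{cond_a}_vs_{cond_b}"
        diff = scoring.differential_reactions(
            (pa["scores"], pa["samples"]), (pb["scores"], pb["samples"])
        )
        tables[f"scores/differential_{tag}.tsv"] = diff

        mapping = projection.gene_reaction_map(universal)
        gene_diff = projection.project_scores(diff, mapping, config.aggregation)
        tables[f"scores/genes_{tag}.tsv"] = gene_diff
        tables[f"scores/gene_reaction_long_{tag}.tsv"] = projection.gene_reaction_long_table(
            diff, mapping
        ).set_index("gene")

        signatures = {}
        for direction in ("a_over_b", "b_over_a"):
            sig = projection.select_signature_genes(
                gene_diff, config.delta_threshold, config.p_threshold, direction
            )
            label = tag if direction == "a_over_b" else f"{cond_b}_vs_{cond_a}"
            write_gene_list(sig, out / "scores" / f"signature_{label}.txt")
            signatures[direction] = sig
        manifest["stages"][tag] = {
            "signature_a_over_b": signatures["a_over_b"],
            "signature_b_over_a": signatures["b_over_a"],
        }

        universe = frozenset(model_genes(pa["model"])) | frozenset(model_genes(pb["model"]))
        for gmt_path in config.gmt_paths:
            collection = enrich_mod.read_gmt(gmt_path)
            stem = Path(gmt_path).stem
            selected = frozenset(signatures["a_over_b"]) & universe
            tables[f"enrichment/ora_{tag}_{stem}.tsv"] = enrich_mod.ora(
                selected, universe, collection
            ).set_index("set_name")
            ranked = gene_diff["delta_usage_gene"]
            tables[f"enrichment/gsea_{tag}_{stem}.tsv"] = enrich_mod.gsea_preranked(
                ranked, collection, seed=_condition_seed(config.seed, 9999)
            ).set_index("set_name")

        tables[f"report/ma_{tag}.tsv"] = reporting.build_ma_table(
            expr, gene_diff, (cond_a, cond_b)
        )
        if de is not None:
            tables[f"report/volcano_{tag}.tsv"] = reporting.build_volcano_table(
                de, gene_diff, config.fc_threshold
            )

    manifest["wall_time_s"] = round(time.time() - t0, 2)
    reporting.write_report(
        out,
        tables,
        manifest,
        input_paths={
            "model": config.model_path,
            "counts": config.counts_path,
            "design": config.design_path,
            "de_table": config.de_table_path,
            "medium": config.medium_path,
        },
        figures=config.figures,
    )
    return out
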