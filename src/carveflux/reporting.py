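"""Plot-ready tables and the run report directory.

The two integrated visual surfaces are emitted as TSVs whose columns match
the plots' axes (an interactive viewer or any plotting tool can consume
them directly):

* the MA-like table — mean log2 expression of each model gene against the
  differential of its projected mean-flux usage between two conditions;
* the flux-weighted volcano table — an external differential-expression
  table (log2 fold change, p-value) joined to the projected usage
  difference, which becomes the point-size weight.

Optional static matplotlib figures are a convenience; the TSVs are the
product.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import ExpressionMatrix, compute_cpm

__all__ = [
    "build_ma_table",
    "build_volcano_table",
    "read_de_table",
    "write_report",
    "save_figures",
]

logger = logging.getLogger(__name__)


def build_ma_table(
    expr: ExpressionMatrix,
    gene_scores: pd.DataFrame,
    conditions: tuple[str, str],
    highlight: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """MA-like table: mean log2(CPM+1) over both conditions' samples versus
    the projected differential flux usage, per model gene."""
    samples = expr.samples_of(conditions[0]) + expr.samples_of(conditions[1])
    log_cpm = np.log2(compute_cpm(expr.counts[samples]) + 1.0)
    mean_expr = log_cpm.mean(axis=1)
    common = gene_scores.index.intersection(mean_expr.index)
    dropped = len(gene_scores) - len(common)
    if dropped:
        logger.info("%d scored genes absent from the count table (dropped)", dropped)
    if len(common) == 0:
        raise ValueError(
            "no gene id is shared between counts and gene scores; are the "
            "counts keyed on the model's gene namespace?"
        )
    out = pd.DataFrame(
        {
            "mean_expression": mean_expr.loc[common],
            "delta_usage_gene": gene_scores.loc[common, "delta_usage_gene"],
            "pathway_flag": [g in highlight for g in common],
        },
        index=common,
    )
    out.index.name = "gene"
    return out.sort_index()


def read_de_table(path: str | Path) -> pd.DataFrame:
    """External differential-expression TSV with columns gene, log2_fc, p_value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2_fc", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table lacks required column(s): {sorted(missing)}")
    return df.set_index("gene")


def build_volcano_table(
    de: pd.DataFrame,
    gene_scores: pd.DataFrame,
    fc_threshold: float = 1.0,
    highlight: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Volcano table: DE statistics sized by |projected flux difference|.

    Genes absent from both carved models keep size_weight 0; ``fc_flag``
    marks |log2_fc| > fc_threshold (default 1, i.e. one absolute fold
    change).
    """
    out = de.copy()
    delta = gene_scores["delta_usage_gene"] if "delta_usage_gene" in gene_scores else None
    out["size_weight"] = (
        delta.reindex(out.index).fillna(0.0).abs() if delta is not None else 0.0
    )
    out["fc_flag"] = out["log2_fc"].abs() > fc_threshold
    out["pathway_flag"] = [g in highlight for g in out.index]
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    outdir: str | Path,
    tables: dict[str, pd.DataFrame],
    manifest: dict,
    input_paths: dict[str, str | Path] | None = None,
    figures: bool = False,
) -> Path:
    """Persist all plot-ready tables plus a machine-readable run manifest.

    ``tables`` maps relative TSV paths (e.g. ``"scores/reactions_A.tsv"``)
    to DataFrames; ``manifest`` carries configuration, seeds and stage
    status and is augmented with package versions and input checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rel, df in tables.items():
        target = outdir / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(target, sep="\t", float_format="%.10g")
    import cobra as _cobra

    from . import __version__

    manifest = dict(manifest)
    manifest["versions"] = {
        "carveflux": __version__,
        "cobra": _cobra.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if input_paths:
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in input_paths.items()
            if p is not None and Path(p).exists()
        }
    (outdir / "report").mkdir(exist_ok=True)
    (outdir / "report" / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if figures:
        save_figures(outdir, tables)
    return outdir


def save_figures(outdir: str | Path, tables: dict[str, pd.DataFrame]) -> None:
    """Optional static figures for any MA / volcano / RCC-histogram tables present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    fig_dir = outdir / "report"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for rel, df in tables.items():
        stem = Path(rel).stem
        fig, ax = plt.subplots(figsize=(5, 4))
        if {"mean_expression", "delta_usage_gene"} <= set(df.columns):
            ax.scatter(df["mean_expression"], df["delta_usage_gene"],
                       c=df["pathway_flag"].map({True: "crimson", False: "grey"}), s=12)
            ax.set_xlabel("mean log2(CPM+1)")
            ax.set_ylabel("Δ mean flux usage")
        elif {"log2_fc", "p_value", "size_weight"} <= set(df.columns):
            ax.scatter(df["log2_fc"], -np.log10(df["p_value"].clip(lower=1e-300)),
                       s=5 + 40 * df["size_weight"] / max(df["size_weight"].max(), 1e-12),
                       c=df["pathway_flag"].map({True: "crimson", False: "grey"}))
            ax.set_xlabel("log2 fold change")
            ax.set_ylabel("-log10 p")
        elif {"bin_left", "bin_right", "count"} <= set(df.columns):
            ax.bar(df["bin_left"], df["count"],
                   width=df["bin_right"] - df["bin_left"], align="edge")
            ax.set_xlabel("RCC")
            ax.set_ylabel("reactions")
        else:
            plt.close(fig)
            continue
        ax.set_title(stem)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{stem}.png", dpi=120)
        plt.close(fig)
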