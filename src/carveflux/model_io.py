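"""Read and write genome-scale metabolic models (SBML L3/fbc and COBRA JSON).

The in-memory container is :class:`cobra.Model`; the biomass reaction is the
model's linear objective.  All downstream stages (carving, sampling, scoring)
take a cobra model plus the biomass reaction id resolved here.
"""

from __future__ import annotations

import os
from pathlib import Path

import cobra
from cobra.util.solver import linear_reaction_coefficients

from .gpr import GprError, parse_gpr

__all__ = [
    "ModelFormatError",
    "read_model",
    "write_model",
    "biomass_id",
    "set_biomass",
    "model_genes",
    "infer_dialect",
]


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or lacks required structure."""


def infer_dialect(path: str | os.PathLike) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ModelFormatError(
        f"cannot infer model dialect from {path!r}; expected a .json, .xml or .sbml file"
    )


def read_model(
    path: str | os.PathLike,
    dialect: str | None = None,
    biomass: str | None = None,
) -> cobra.Model:
    """Read a metabolic model, validate it and designate its biomass reaction.

    Parameters
    ----------
    path
        Model file (SBML Level 3 with fbc, or COBRA-style JSON).
    dialect
        ``"sbml"`` or ``"json"``; inferred from the file suffix when omitted.
    biomass
        Reaction id to use as biomass.  When omitted the model's objective
        reaction is used; an error instructs the user to pass ``--biomass``
        if neither is available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or infer_dialect(path)
    try:
        if dialect == "json":
            model = cobra.io.load_json_model(str(path))
        elif dialect == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model dialect {dialect!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # cobra/libsbml raise a zoo of exception types
        raise ModelFormatError(f"cannot parse {path} as {dialect}: {exc}") from exc

    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelFormatError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        try:
            parse_gpr(rxn.gene_reaction_rule)
        except GprError as exc:
            raise ModelFormatError(f"reaction {rxn.id!r}: bad GPR: {exc}") from exc

    if biomass is not None:
        set_biomass(model, biomass)
    elif biomass_id(model, required=False) is None:
        raise ModelFormatError(
            f"{path} designates no objective/biomass reaction; "
            "pass --biomass <reaction id>"
        )
    return model


def write_model(model: cobra.Model, path: str | os.PathLike, dialect: str | None = None) -> None:
    """Write a model as SBML L3/fbc or COBRA JSON (dialect inferred from suffix)."""
    path = Path(path)
    dialect = dialect or infer_dialect(path)
    if dialect == "json":
        cobra.io.save_json_model(model, str(path))
    elif dialect == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ModelFormatError(f"unknown model dialect {dialect!r}")


def biomass_id(model: cobra.Model, required: bool = True) -> str | None:
    """Return the id of the model's biomass (objective) reaction."""
    coeffs = linear_reaction_coefficients(model)
    for rxn, coef in coeffs.items():
        if coef != 0:
            return rxn.id
    if required:
        raise ModelFormatError(
            f"model {model.id!r} has no objective reaction; call set_biomass first"
        )
    return None


def set_biomass(model: cobra.Model, reaction_id: str) -> None:
    if reaction_id not in model.reactions:
        raise ModelFormatError(
            f"biomass reaction {reaction_id!r} not found in model {model.id!r}"
        )
    model.objective = reaction_id


def model_genes(model: cobra.Model) -> frozenset[str]:
    """Union of gene ids over all GPR rules (parsed, not taken from annotations)."""
    out: frozenset[str] = frozenset()
    for rxn in model.reactions:
        expr = parse_gpr(rxn.gene_reaction_rule)
        if expr is not None:
            out |= expr.genes()
    return out
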