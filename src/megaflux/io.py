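"""Model serialization (SBML L3+FBC, a JSON dialect) and tabular output.

SBML reading and writing is delegated to cobra (libSBML underneath), with
conversion to and from this package's domain types; FBC v2
bounds-as-parameters is the write format and per-reaction embedded bounds
are accepted on read.  The JSON dialect is a flat, lossless dump of every
field the package models:

.. code-block:: json

    {
      "id": "toy_core",
      "metabolites": [{"id": "A_e", "name": "...", "compartment": "e",
                       "formula": "C6H12O6"}],
      "reactions":   [{"id": "EX_A", "name": "...", "subsystem": "",
                       "stoichiometry": {"A_e": -1.0},
                       "lower_bound": -10.0, "upper_bound": 1000.0,
                       "gpr": "(g2 and g3) or g4"}],
      "genes": ["g1"],
      "objective": {"GROWTH": 1.0},
      "hypothetical": []
    }

Metabolite ids written in the bracketed style ``"G6P[c]"`` are recognized:
the suffix is stripped into the compartment field on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .fluxsum import FluxSumResult
from .gpr import parse_gpr
from .lp import FVAResult
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ModelDocument",
    "ModelIOError",
    "read_sbml",
    "write_sbml",
    "read_json",
    "write_json",
    "read_model",
    "write_table",
    "split_bracket_suffix",
]


class ModelIOError(ValueError):
    """A model file could not be parsed or serialized."""


@dataclass
class ModelDocument:
    """A parsed model plus its provenance (source path, format, dialect notes)."""

    model: MetabolicModel
    source: str = ""
    format: str = ""
    notes: str = ""


def split_bracket_suffix(met_id: str) -> Tuple[str, Optional[str]]:
    """Split ``"G6P[c]"`` into ``("G6P", "c")``; ids without a bracket pass through."""
    if met_id.endswith("]") and "[" in met_id:
        base, _, comp = met_id[:-1].rpartition("[")
        if base and comp:
            return base, comp
    return met_id, None


# ---------------------------------------------------------------------------
# SBML via cobra


def _to_cobra(model: MetabolicModel):
    import cobra
    from cobra.util.solver import set_objective

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula or None
        )
        for m in model.metabolites
    }
    crxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, name=rxn.name, subsystem=rxn.subsystem)
        cr.add_metabolites({mets[mid]: coeff for mid, coeff in rxn.stoichiometry.items()})
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for rxn, cr in zip(model.reactions, crxns):
        if not rxn.gpr.is_empty:
            cr.gene_reaction_rule = rxn.gpr.to_string()
    if model.objective:
        set_objective(
            cm, {cm.reactions.get_by_id(rid): coeff for rid, coeff in model.objective.items()}
        )
    return cm


def _from_cobra(cm, source: str = "") -> ModelDocument:
    metabolites = []
    for met in cm.metabolites:
        met_id, bracket_comp = split_bracket_suffix(met.id)
        comp = met.compartment or bracket_comp or "c"
        metabolites.append(
            Metabolite(
                id=met.id if met.compartment else met_id,
                name=met.name or "",
                compartment=comp,
                formula=met.formula or "",
            )
        )
    id_map = {met.id: new.id for met, new in zip(cm.metabolites, metabolites)}
    reactions = []
    objective: Dict[str, float] = {}
    for cr in cm.reactions:
        reactions.append(
            Reaction(
                id=cr.id,
                name=cr.name or "",
                stoichiometry={id_map[m.id]: float(c) for m, c in cr.metabolites.items()},
                lower_bound=float(cr.lower_bound),
                upper_bound=float(cr.upper_bound),
                gpr=parse_gpr(cr.gene_reaction_rule or ""),
                subsystem=cr.subsystem or "",
            )
        )
        coeff = float(cr.objective_coefficient)
        if coeff:
            objective[cr.id] = coeff
    if not objective:
        warnings.warn(f"{source or cm.id}: no objective found; leaving it empty")
    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(g.id for g in cm.genes),
        objective=objective,
    )
    model.validate()
    return ModelDocument(model=model, source=source, format="sbml", notes="read via cobra/libSBML")


def read_sbml(path: Union[str, Path]) -> ModelDocument:
    """Read an SBML Level 3 + FBC model (other common dialects accepted).

    Missing objectives produce a warning and an empty objective; structural
    problems (dangling species references, truncated files) raise
    :class:`ModelIOError` naming the offender.
    """
    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cobra is chatty about missing annotations
            cm = read_sbml_model(str(path))
    except Exception as exc:  # libSBML raises many concrete types
        raise ModelIOError(f"could not parse SBML file {path}: {exc}") from exc
    return _from_cobra(cm, source=str(path))


def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Write the model as SBML L3 + FBC v2 (bounds as parameters)."""
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(Path(path)))


# ---------------------------------------------------------------------------
# JSON dialect


def write_json(model: MetabolicModel, path: Union[str, Path]) -> None:
    payload = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment, "formula": m.formula}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective": {k: float(v) for k, v in model.objective.items()},
        "hypothetical": sorted(model.hypothetical),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_json(path: Union[str, Path]) -> ModelDocument:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"could not parse JSON model {path}: {exc}") from exc
    try:
        metabolites = []
        renames: Dict[str, str] = {}
        for m in payload["metabolites"]:
            met_id, bracket_comp = split_bracket_suffix(m["id"])
            comp = m.get("compartment") or bracket_comp or "c"
            final_id = m["id"] if m.get("compartment") else met_id
            renames[m["id"]] = final_id
            metabolites.append(
                Metabolite(id=final_id, name=m.get("name", ""), compartment=comp,
                           formula=m.get("formula", ""))
            )
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={renames.get(k, k): float(v)
                               for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
            )
            for r in payload["reactions"]
        ]
        model = MetabolicModel(
            id=payload.get("id", path.stem),
            metabolites=metabolites,
            reactions=reactions,
            genes=list(payload.get("genes", [])),
            objective={k: float(v) for k, v in payload.get("objective", {}).items()},
            hypothetical=set(payload.get("hypothetical", [])),
        )
    except (KeyError, TypeError) as exc:
        raise ModelIOError(f"malformed JSON model {path}: missing field {exc}") from exc
    if not model.genes:
        inferred = set()
        for rxn in model.reactions:
            inferred |= rxn.gpr.genes()
        model.genes = sorted(inferred)
    if not model.objective:
        warnings.warn(f"{path}: no objective found; leaving it empty")
    model.validate()
    return ModelDocument(model=model, source=str(path), format="json")


def read_model(path: Union[str, Path]) -> ModelDocument:
    """Dispatch on extension: ``.json`` -> JSON dialect, else SBML."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_json(path)
    return read_sbml(path)


# ---------------------------------------------------------------------------
# Tabular output


def _as_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result  # caller-prepared frame: columns are already in order
    if isinstance(result, FVAResult):
        rows = [
            {"reaction": rid, "min": lo, "max": hi}
            for rid, (lo, hi) in sorted(result.intervals.items())
        ]
        return pd.DataFrame(rows, columns=["reaction", "min", "max"])
    if isinstance(result, FluxSumResult):
        rows = [{"metabolite": mid, "flux_sum": phi}
                for mid, phi in sorted(result.values.items())]
        return pd.DataFrame(rows, columns=["metabolite", "flux_sum"])
    if isinstance(result, dict):  # a FluxDistribution
        rows = [{"reaction": rid, "flux": v} for rid, v in sorted(result.items())]
        return pd.DataFrame(rows, columns=["reaction", "flux"])
    raise TypeError(f"don't know how to tabulate {type(result).__name__}")


def write_table(result, path: Union[str, Path]) -> None:
    """Write an analysis result as TSV: deterministic row/column order,
    header row, floats at 6 significant digits.  Empty results produce a
    header-only file."""
    frame = _as_frame(result)
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")
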