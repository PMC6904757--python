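"""Domain types for constraint-based metabolic models.

The central object is :class:`MetabolicModel`: metabolites, reactions with
flux bounds (mmol/gDW/h) and GPR associations, and a linear objective
(typically the biomass pseudo-reaction, whose flux approximates the specific
growth rate in 1/h).

Sign convention for exchange reactions: a negative flux is uptake, a
positive flux secretion.  A :class:`Medium` therefore stores *positive*
uptake magnitudes; applying it sets the exchange lower bound to minus that
magnitude and closes uptake of everything else.
"""

from __future__ import annotations

import copy as _copy
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
from scipy import sparse

from .gpr import EMPTY_GPR, GPRExpression, gpr_active, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Medium",
    "ModelValidationError",
    "knockout_genes",
    "knockout_reactions",
    "apply_medium",
    "add_hypothetical_transporter",
    "build_stoich_matrix",
    "model_stats",
    "carbon_count",
]

#: Default magnitude used for unconstrained flux bounds.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """An invariant of the model data structure is violated."""


@dataclass
class Metabolite:
    """A chemical species in a compartment (``"c"`` cytosol, ``"e"`` extracellular)."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id}: compartment must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR gate.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  Bounds are in mmol/gDW/h.  A reaction with a single
    metabolite is a boundary (exchange) reaction.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gpr: GPRExpression = field(default_factory=lambda: EMPTY_GPR)
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)

    @property
    def reversibility(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction touching exactly one metabolite.

        Some SBML dialects also mark exchanges with an ``EX_`` id prefix; in
        every such dialect the reaction still has a single (non-boundary)
        species once boundary species are stripped, so the single-metabolite
        rule is the one applied.
        """
        return len(self.stoichiometry) == 1


Medium = Mapping[str, float]
"""Exchange-reaction id -> allowed uptake magnitude (>= 0, mmol/gDW/h)."""


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model.

    ``objective`` maps reaction ids to linear weights c_j; FBA maximizes
    ``sum_j c_j v_j`` subject to steady state ``S v = 0`` and the bounds.
    ``hypothetical`` records ids of interim transport/exchange reactions
    added for single-carbon-source screens, so they can be scoped to the
    run that needed them.
    """

    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)
    hypothetical: Set[str] = field(default_factory=set)

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(f"no metabolite {met_id!r} in model {self.id}")

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id}")

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for rxn in self.reactions:
            dangling = set(rxn.stoichiometry) - met_set
            if dangling:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolites: {sorted(dangling)}"
                )
            missing = rxn.gpr.genes() - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id} GPR uses unregistered genes: {sorted(missing)}"
                )
        unknown_obj = set(self.objective) - set(rxn_ids)
        if unknown_obj:
            raise ModelValidationError(
                f"objective references unknown reactions: {sorted(unknown_obj)}"
            )


# ---------------------------------------------------------------------------
# Operations


def knockout_genes(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Close every reaction whose GPR evaluates inactive after deleting ``genes``.

    Reactions are never removed -- both bounds are set to zero -- so the same
    model supports repeated what-if queries.  Reactions with an empty GPR or
    a surviving isozyme are untouched.
    """
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"genes not in model: {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.gpr.is_empty and not gpr_active(rxn.gpr, genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def knockout_reactions(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Set both bounds of the listed reactions to zero (returns a copy)."""
    ids = set(reaction_ids)
    out = model.copy()
    known = {r.id for r in out.reactions}
    unknown = ids - known
    if unknown:
        raise KeyError(f"reactions not in model: {sorted(unknown)}")
    for rxn in out.reactions:
        if rxn.id in ids:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Constrain uptake to the given medium (returns a copy).

    Every exchange reaction's lower bound is set to 0 (no uptake) unless it
    appears in ``medium``, in which case the lower bound becomes minus the
    stated uptake magnitude.  Secretion (upper) bounds are untouched.
    Idempotent: applying the same medium twice yields identical bounds.
    """
    exchange_ids = {r.id for r in model.reactions if r.is_exchange}
    for key, value in medium.items():
        if key not in exchange_ids:
            raise KeyError(f"medium component {key!r} is not an exchange reaction")
        if value < 0:
            raise ValueError(f"medium uptake for {key!r} must be >= 0, got {value}")
    out = model.copy()
    for rxn in out.reactions:
        if rxn.is_exchange:
            rxn.lower_bound = -float(medium.get(rxn.id, 0.0))
    return out


def _base_id(met: Metabolite) -> str:
    suffix = "_" + met.compartment
    return met.id[: -len(suffix)] if met.id.endswith(suffix) else met.id


def add_hypothetical_transporter(model: MetabolicModel, metabolite_id: str) -> MetabolicModel:
    """Add an interim transport + exchange pair for an intracellular metabolite.

    Used when screening growth on a carbon source that has no known carrier:
    an extracellular twin species, a reversible transporter with no gene
    association, and an exchange reaction are added, all flagged as
    hypothetical so callers can scope them to a single simulation.
    """
    met = model.metabolite(metabolite_id)
    if met.compartment == "e":
        raise ValueError(f"{metabolite_id} is already extracellular")
    base = _base_id(met)
    ext_id, transport_id, exchange_id = f"{base}_e", f"T_{base}", f"EX_{base}_e"
    for existing in (ext_id,):
        if model.has_metabolite(existing):
            raise ValueError(f"transporter for {metabolite_id} already exists ({existing})")
    for existing in (transport_id, exchange_id):
        if model.has_reaction(existing):
            raise ValueError(f"transporter for {metabolite_id} already exists ({existing})")
    out = model.copy()
    out.metabolites.append(
        Metabolite(id=ext_id, name=met.name or base, compartment="e", formula=met.formula)
    )
    out.reactions.append(
        Reaction(
            id=transport_id,
            name=f"{base} transport (hypothetical)",
            stoichiometry={ext_id: -1.0, metabolite_id: 1.0},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
        )
    )
    out.reactions.append(
        Reaction(
            id=exchange_id,
            name=f"{base} exchange (hypothetical)",
            stoichiometry={ext_id: -1.0},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
        )
    )
    out.hypothetical |= {transport_id, exchange_id}
    return out


def build_stoich_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """Assemble the stoichiometric matrix S (metabolites x reactions).

    S[i, j] is the coefficient of metabolite i in reaction j; steady state
    is S v = 0.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def model_stats(model: MetabolicModel) -> Dict[str, float]:
    """Headline model statistics.

    ``pct_gene_associated_excluding_exchange`` is 100 x the share of
    non-exchange reactions carrying a non-empty GPR, rounded to 0 decimals.
    """
    internal = [r for r in model.reactions if not r.is_exchange]
    n_exchange = len(model.reactions) - len(internal)
    with_gpr = sum(1 for r in internal if not r.gpr.is_empty)
    pct = 100.0 * with_gpr / len(internal) if internal else math.nan
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(model.genes),
        "n_exchange": n_exchange,
        "pct_gene_associated_excluding_exchange": round(pct) if internal else pct,
    }


_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count(formula: str) -> Optional[int]:
    """Number of carbon atoms in a chemical formula, or None when unparseable.

    Element symbols are one capital plus optional lowercase (so Cl/Ca/Co are
    not miscounted as carbon).
    """
    if not formula:
        return None
    pos, carbons = 0, 0
    for match in _ELEMENT.finditer(formula):
        if match.start() != pos or not match.group(0):
            return None
        pos = match.end()
        if match.group(1) == "C":
            carbons += int(match.group(2) or 1)
    if pos != len(formula):
        return None
    return carbons
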