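"""Mutant production simulations and dose-response scans.

Two analyses built on FBA:

* the two-stage production protocol — maximize biomass, then hold growth at
  >= a fraction of that optimum and maximize a target flux (e.g. the
  shikimate dehydrogenase flux in a shikimate-kinase knockout);
* step-wise dose-response scans — force the uptake of a compound (e.g.
  formaldehyde) through an increasing grid and record the biomass optimum at
  each step, distinguishing inert/detoxified compounds (flat curve) from
  assimilated ones (rising curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .lp import _STATUS, _bounds, _objective_vector, solve_fba
from .model import MetabolicModel, Medium, apply_medium, build_stoich_matrix, knockout_genes

__all__ = [
    "ProductionResult",
    "DoseResponseCurve",
    "production_capacity",
    "carbon_source_panel",
    "dose_response_scan",
]


@dataclass
class ProductionResult:
    """Outcome of a two-stage growth-then-production simulation."""

    target: str
    mu_max: float
    production: float
    fraction: float
    source: str = ""
    status: str = "optimal"


@dataclass
class DoseResponseCurve:
    """Biomass optimum as a function of a forced uptake flux."""

    exchange: str
    doses: List[float]
    biomass: List[float]
    statuses: List[str] = field(default_factory=list)


def production_capacity(
    model: MetabolicModel, target_reaction_id: str, fraction: float = 0.9
) -> ProductionResult:
    """Maximum target flux while growth stays at >= ``fraction`` of its optimum.

    Stage 1 maximizes the model's own (biomass) objective, giving mu_max;
    stage 2 maximizes the flux through ``target_reaction_id`` subject to the
    additional constraint c' v >= fraction * mu_max.  An infeasible stage 1
    yields mu_max = 0 and production 0.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    index = {r.id: j for j, r in enumerate(model.reactions)}
    if target_reaction_id not in index:
        raise KeyError(f"no reaction {target_reaction_id!r} in model")
    stage1 = solve_fba(model)
    if not stage1.ok:
        return ProductionResult(
            target=target_reaction_id,
            mu_max=0.0,
            production=0.0,
            fraction=fraction,
            status=stage1.status,
        )
    mu_max = stage1.objective_value
    c = _objective_vector(model)
    e = np.zeros(len(model.reactions))
    e[index[target_reaction_id]] = 1.0
    res = linprog(
        -e,
        A_eq=build_stoich_matrix(model),
        b_eq=np.zeros(len(model.metabolites)),
        A_ub=(-c)[None, :],
        b_ub=np.array([-fraction * mu_max]),
        bounds=_bounds(model),
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    production = float(res.x[index[target_reaction_id]]) if res.status == 0 else 0.0
    return ProductionResult(
        target=target_reaction_id,
        mu_max=float(mu_max),
        production=production if production > 0 else 0.0,
        fraction=fraction,
        status=status,
    )


def carbon_source_panel(
    model: MetabolicModel,
    knockouts: Iterable[str],
    sources_with_uptakes: Mapping[str, float],
    target_reaction_id: str,
    fraction: float = 0.9,
    base_medium: Optional[Medium] = None,
) -> List[ProductionResult]:
    """Two-stage production across carbon sources for a knockout strain.

    The gene knockouts are applied once; then, per source (exchange id ->
    uptake magnitude, e.g. estimated from batch time courses), the base
    medium plus that single source is applied and
    :func:`production_capacity` run.  Results keep the source order given.
    """
    mutant = knockout_genes(model, set(knockouts)) if knockouts else model
    base = dict(base_medium or {})
    results = []
    for exchange_id, uptake in sources_with_uptakes.items():
        conditioned = apply_medium(mutant, {**base, exchange_id: float(uptake)})
        result = production_capacity(conditioned, target_reaction_id, fraction=fraction)
        result.source = exchange_id
        results.append(result)
    return results


def dose_response_scan(
    model: MetabolicModel,
    exchange_id: str,
    doses: Sequence[float],
) -> DoseResponseCurve:
    """Biomass optimum under a forced, step-wise increasing uptake flux.

    ``doses`` must be non-negative and strictly increasing.  At each dose d
    the exchange reaction's lower *and* upper bounds are pinned to -d, so
    uptake is obligatory — with a free lower bound the solver would simply
    decline a toxic compound.  Infeasible doses are recorded as such with
    biomass 0.
    """
    doses = [float(d) for d in doses]
    if not doses:
        raise ValueError("dose grid must contain at least one value")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("dose grid must be strictly increasing")
    rxn = model.reaction(exchange_id)  # raises KeyError when absent
    if not rxn.is_exchange:
        raise ValueError(f"{exchange_id} is not an exchange reaction")
    curve = DoseResponseCurve(exchange=exchange_id, doses=doses, biomass=[], statuses=[])
    for dose in doses:
        dosed = model.copy()
        target = dosed.reaction(exchange_id)
        target.lower_bound = -dose
        target.upper_bound = -dose
        result = solve_fba(dosed)
        curve.biomass.append(result.objective_value if result.ok else 0.0)
        curve.statuses.append(result.status)
    return curve
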