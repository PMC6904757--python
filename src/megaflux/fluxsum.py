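"""Metabolite turnover (flux-sum) analysis.

The flux-sum of metabolite i under a steady-state flux distribution v is

    phi_i = 1/2 * sum_j |S_ij v_j|

which equals the metabolite's total production rate (= total consumption
rate).  Because alternate FBA optima make phi ambiguous, profiles are
computed on the minimum-total-flux distribution by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lp import FluxDistribution, min_total_flux, solve_fba
from .model import MetabolicModel, Medium, apply_medium, build_stoich_matrix, carbon_count

__all__ = [
    "FluxSumResult",
    "FluxSumProfile",
    "compute_flux_sum",
    "flux_sum_profile",
    "normalize_rows",
]


@dataclass
class FluxSumResult:
    """phi per metabolite (mmol/gDW/h) plus the distribution it came from."""

    values: Dict[str, float]
    fluxes: FluxDistribution

    def __getitem__(self, met_id: str) -> float:
        return self.values[met_id]


@dataclass
class FluxSumProfile:
    """Metabolites x conditions matrix of flux-sum values.

    ``normalized`` (when present) divides each row by its maximum so the
    per-metabolite profile across carbon sources peaks at 1.
    """

    table: pd.DataFrame
    normalized: Optional[pd.DataFrame] = None


def compute_flux_sum(model: MetabolicModel, fluxes: FluxDistribution) -> FluxSumResult:
    """Evaluate phi_i = 1/2 sum_j |S_ij v_j| for every metabolite.

    ``fluxes`` must satisfy steady state (checked to 1e-6); phi then equals
    both the total production and the total consumption of each metabolite,
    and is zero for metabolites untouched by active reactions.
    """
    S = build_stoich_matrix(model)
    v = np.array([fluxes[r.id] for r in model.reactions])
    if v.size:
        residual = np.max(np.abs(S @ v))
        if residual > 1e-6:
            raise ValueError(f"distribution violates steady state (|Sv|_inf = {residual:.3g})")
    if v.size:
        phi = 0.5 * np.asarray(np.abs(S.multiply(v)).sum(axis=1)).ravel()
    else:
        phi = np.zeros(S.shape[0])
    return FluxSumResult(
        values={m.id: float(p) for m, p in zip(model.metabolites, phi)},
        fluxes=dict(fluxes),
    )


def _source_metabolite(model: MetabolicModel, exchange_id: str):
    rxn = model.reaction(exchange_id)
    if not rxn.is_exchange:
        raise ValueError(f"{exchange_id} is not an exchange reaction")
    (met_id,) = rxn.stoichiometry
    return model.metabolite(met_id)


def flux_sum_profile(
    model: MetabolicModel,
    base_medium: Medium,
    carbon_sources: Sequence[str],
    carbon_basis: float = 1.0,
    fraction: float = 1.0,
    carbon_counts: Optional[Mapping[str, int]] = None,
    normalize: bool = False,
) -> FluxSumProfile:
    """Flux-sum profile across sole carbon sources at a fixed carbon basis.

    Each source (given by its exchange-reaction id) is allowed an uptake of
    ``carbon_basis`` mmol carbon/gDW/h, i.e. an exchange bound of
    basis / (carbon atoms per molecule), on top of ``base_medium``.  Carbon
    counts come from metabolite formulas when present, else from the
    ``carbon_counts`` table keyed by metabolite id.  Per source the model is
    solved by FBA, the distribution disambiguated by total-flux minimization
    at ``fraction``, and phi computed.
    """
    carbon_counts = dict(carbon_counts or {})
    columns: Dict[str, Dict[str, float]] = {}
    for exchange_id in carbon_sources:
        met = _source_metabolite(model, exchange_id)
        n_carbon = carbon_count(met.formula)
        if n_carbon is None:
            n_carbon = carbon_counts.get(met.id)
        if not n_carbon:
            raise ValueError(
                f"unknown carbon count for metabolite {met.id!r} "
                f"(source {exchange_id}); supply carbon_counts"
            )
        uptake = carbon_basis / n_carbon
        conditioned = apply_medium(model, {**dict(base_medium), exchange_id: uptake})
        result = solve_fba(conditioned)
        if not result.ok:
            raise ValueError(f"FBA on source {exchange_id} ended {result.status}")
        fluxes = min_total_flux(conditioned, fraction=fraction)
        columns[exchange_id] = compute_flux_sum(conditioned, fluxes).values
    table = pd.DataFrame(columns, index=[m.id for m in model.metabolites]).fillna(0.0)
    table = table[list(carbon_sources)]
    profile = FluxSumProfile(table=table)
    if normalize:
        profile.normalized = normalize_rows(profile).table
    return profile


def normalize_rows(profile: FluxSumProfile) -> FluxSumProfile:
    """Divide each metabolite row by its maximum; all-zero rows stay zero.

    Idempotent, and the natural scaling for comparing a metabolite's
    turnover across carbon sources.
    """
    table = profile.table
    row_max = table.max(axis=1)
    scale = row_max.where(row_max > 0, 1.0)
    return FluxSumProfile(table=table.div(scale, axis=0))
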