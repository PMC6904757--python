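"""Sole-carbon-source phenotype screening and concordance with growth calls.

Mirrors a Biolog-style validation: for each candidate carbon source an
independent FBA is run on a base (salts-only) medium plus that source as the
only carbon input; the binary growth call is compared with the experimental
plate call, yielding a confusion matrix and an accuracy percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .lp import solve_fba
from .model import (
    MetabolicModel,
    Medium,
    add_hypothetical_transporter,
    apply_medium,
)

__all__ = ["PhenotypeCall", "ConcordanceReport", "screen_carbon_sources", "compare_calls"]

#: growth calls below this biomass flux (1/h) count as no-growth; keeps
#: solver noise from registering as growth
GROWTH_THRESHOLD = 1e-6

#: default sole-carbon-source uptake bound (mmol/gDW/h)
DEFAULT_UPTAKE = 5.0


@dataclass
class PhenotypeCall:
    """Outcome of one sole-carbon-source simulation."""

    source: str
    predicted: bool
    observed: Optional[bool] = None
    used_hypothetical_transporter: bool = False
    growth_rate: float = 0.0
    reason: str = ""


@dataclass
class ConcordanceReport:
    """Confusion counts of predicted vs observed growth calls."""

    tp: int
    tn: int
    fp: int
    fn: int
    discrepancies: List[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        """Percent of calls matching observation: 100 (TP+TN)/n."""
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")


def _find_exchange_for(model: MetabolicModel, metabolite_id: str) -> Optional[str]:
    """Exchange reaction feeding the metabolite's extracellular form.

    Only boundaries on extracellular species qualify: a single-metabolite
    drain on a cytosolic species (e.g. the biomass pseudo-reaction) is not a
    transporter-backed exchange.
    """
    try:
        met = model.metabolite(metabolite_id)
    except KeyError:
        return None
    suffix = "_" + met.compartment
    base = met.id[: -len(suffix)] if met.id.endswith(suffix) else met.id
    for rxn in model.exchange_reactions():
        (ex_met_id,) = rxn.stoichiometry
        ex_met = model.metabolite(ex_met_id)
        if ex_met.compartment != "e":
            continue
        ex_suffix = "_" + ex_met.compartment
        ex_base = ex_met.id[: -len(ex_suffix)] if ex_met.id.endswith(ex_suffix) else ex_met.id
        if ex_met_id == metabolite_id or ex_base == base:
            return rxn.id
    return None


def screen_carbon_sources(
    model: MetabolicModel,
    base_medium: Medium,
    sources: Sequence[str],
    uptake_bound: float = DEFAULT_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
    allow_hypothetical: bool = False,
) -> List[PhenotypeCall]:
    """Simulate growth on each source as the sole carbon input.

    ``sources`` are metabolite ids.  Per source, the base medium (which must
    not itself carry any of the tested carbon sources) is applied, the
    source's exchange lower bound opened to ``-uptake_bound``, and FBA
    solved; growth is called when the optimum exceeds ``growth_threshold``.

    A source without a transporter is called no-growth unless
    ``allow_hypothetical`` is set, in which case an interim transport +
    exchange pair is added *for that run only* and the call is flagged.  A
    source absent from the model altogether is recorded as no-growth with
    reason ``"absent"``.
    """
    calls: List[PhenotypeCall] = []
    for source in sources:
        if not model.has_metabolite(source):
            calls.append(PhenotypeCall(source=source, predicted=False, reason="absent"))
            continue
        working = model
        hypothetical = False
        exchange_id = _find_exchange_for(model, source)
        if exchange_id is None:
            if not allow_hypothetical:
                calls.append(
                    PhenotypeCall(source=source, predicted=False, reason="no transporter")
                )
                continue
            working = add_hypothetical_transporter(model, source)
            exchange_id = _find_exchange_for(working, source)
            hypothetical = True
        conditioned = apply_medium(working, {**dict(base_medium), exchange_id: uptake_bound})
        result = solve_fba(conditioned)
        growth = result.objective_value if result.ok else 0.0
        calls.append(
            PhenotypeCall(
                source=source,
                predicted=bool(growth > growth_threshold),
                used_hypothetical_transporter=hypothetical,
                growth_rate=float(growth),
            )
        )
    return calls


def compare_calls(
    calls: Sequence[PhenotypeCall], observed: Mapping[str, bool]
) -> ConcordanceReport:
    """Confront predicted growth calls with experimental ones.

    Only sources present in ``observed`` enter the confusion counts.
    Discrepant sources are listed in id order.
    """
    tp = tn = fp = fn = 0
    discrepancies: List[str] = []
    for call in calls:
        if call.source not in observed:
            continue
        obs = bool(observed[call.source])
        call.observed = obs
        if call.predicted and obs:
            tp += 1
        elif not call.predicted and not obs:
            tn += 1
        elif call.predicted and not obs:
            fp += 1
            discrepancies.append(call.source)
        else:
            fn += 1
            discrepancies.append(call.source)
    return ConcordanceReport(tp=tp, tn=tn, fp=fp, fn=fn, discrepancies=sorted(discrepancies))
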