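"""Linear-programming analyses of a metabolic model.

All solves go through scipy's HiGHS interface with default (deterministic)
settings.  The core problem is flux balance analysis:

    maximize   Z = c' v
    subject to S v = 0
               lb <= v <= ub

Feasibility is handled at 1e-9 by the solver; reported equalities (steady
state, binding objective constraints) are checked at 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoich_matrix

__all__ = [
    "FBAResult",
    "FVAResult",
    "solve_fba",
    "min_total_flux",
    "fva",
    "normalize_to_reference",
    "interval_contains",
]

FEASIBILITY_TOL = 1e-9
REPORT_TOL = 1e-6

FluxDistribution = Dict[str, float]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class FBAResult:
    """Outcome of one FBA solve.

    ``objective_value`` is in 1/h when the objective is the biomass
    pseudo-reaction, otherwise mmol/gDW/h.  ``fluxes`` is empty unless the
    status is ``optimal``.
    """

    objective_value: float
    fluxes: FluxDistribution
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def steady_state_residual(self, model: MetabolicModel) -> float:
        """Max-norm of S v for the stored distribution (0 when empty)."""
        if not self.fluxes:
            return 0.0
        S = build_stoich_matrix(model)
        v = np.array([self.fluxes[r.id] for r in model.reactions])
        return float(np.max(np.abs(S @ v))) if v.size else 0.0


@dataclass
class FVAResult:
    """Per-reaction admissible flux intervals at a stated objective fraction.

    ``bounded[rid]`` is a (min_bounded, max_bounded) pair; an endpoint is
    flagged unbounded when variability ran into the reaction's own box
    bound, i.e. the network itself does not limit the flux there (typically
    a futile cycle spanning the +/-1000 defaults).
    """

    fraction: float
    intervals: Dict[str, Tuple[float, float]]
    bounded: Dict[str, Tuple[bool, bool]] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.intervals[rid]


def _objective_vector(model: MetabolicModel) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        if rxn.id in model.objective:
            c[j] = model.objective[rxn.id]
    return c


def _bounds(model: MetabolicModel) -> List[Tuple[float, float]]:
    return [(r.lower_bound, r.upper_bound) for r in model.reactions]


def _solve(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    bounds: Sequence[Tuple[float, float]],
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    maximize: bool = True,
):
    res = linprog(
        -c if maximize else c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(bounds),
        method="highs",
    )
    return res


def solve_fba(model: MetabolicModel) -> FBAResult:
    """Maximize the model objective subject to steady state and bounds.

    Infeasible or unbounded problems are reported through the ``status``
    field, never raised.  With alternate optima the returned distribution is
    solver-dependent; use :func:`min_total_flux` for a canonical one.
    """
    if not model.objective:
        raise ValueError("model has an empty objective; nothing to maximize")
    if not model.reactions:
        return FBAResult(0.0, {}, "optimal")
    c = _objective_vector(model)
    res = _solve(c, build_stoich_matrix(model), _bounds(model))
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        value = math.inf if status == "unbounded" else 0.0
        return FBAResult(value, {}, status)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FBAResult(float(c @ res.x), fluxes, "optimal")


def _objective_floor_row(
    model: MetabolicModel, fraction: float, z_star: float
) -> Tuple[np.ndarray, float]:
    """Inequality row encoding c' v >= fraction * Z* as -c' v <= -f Z*."""
    c = _objective_vector(model)
    return -c, -fraction * z_star


def min_total_flux(model: MetabolicModel, fraction: float = 1.0) -> FluxDistribution:
    """Minimum-total-flux distribution at a given objective fraction.

    Solves ``min sum_j |v_j|`` subject to steady state, the bounds, and
    ``c' v >= fraction * Z*`` where Z* is the FBA optimum.  The absolute
    values are linearized by splitting each flux into non-negative forward
    and reverse parts.  This suppresses futile cycles and disambiguates
    alternate optima, giving the distribution used for flux-sum turnover.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ref = solve_fba(model)
    if not ref.ok:
        raise ValueError(f"FBA did not reach an optimum (status {ref.status})")
    n = len(model.reactions)
    S = build_stoich_matrix(model)
    # v = p - q with exact box bounds: the split reproduces [lb, ub] even for
    # reactions forced to run (lb > 0) or to reverse (ub < 0).
    p_bounds = [(max(r.lower_bound, 0.0), max(r.upper_bound, 0.0)) for r in model.reactions]
    q_bounds = [(max(-r.upper_bound, 0.0), max(-r.lower_bound, 0.0)) for r in model.reactions]
    A_eq = sparse.hstack([S, -S], format="csr")
    row, rhs = _objective_floor_row(model, fraction, ref.objective_value)
    A_ub = np.concatenate([row, -row])[None, :]
    cost = np.ones(2 * n)
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=np.array([rhs]),
        bounds=p_bounds + q_bounds,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"total-flux minimization failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    return {r.id: float(x) for r, x in zip(model.reactions, v)}


def fva(
    model: MetabolicModel,
    fraction: float = 0.9,
    reactions: Optional[Sequence[str]] = None,
) -> FVAResult:
    """Flux variability analysis at a stated objective fraction.

    For each reaction, minimizes and maximizes its flux subject to steady
    state, the bounds, and the objective held at >= ``fraction`` of its FBA
    optimum (two LPs per reaction).  ``fraction=0.9`` is the suboptimal
    setting used when confronting predictions with measured fluxes;
    ``fraction=1.0`` restricts to the optimal face.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ref = solve_fba(model)
    if not ref.ok:
        raise ValueError(f"FBA did not reach an optimum (status {ref.status})")
    S = build_stoich_matrix(model)
    bounds = _bounds(model)
    row, rhs = _objective_floor_row(model, fraction, ref.objective_value)
    A_ub, b_ub = row[None, :], np.array([rhs])
    targets = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    index = {r.id: j for j, r in enumerate(model.reactions)}
    intervals: Dict[str, Tuple[float, float]] = {}
    bounded: Dict[str, Tuple[bool, bool]] = {}
    for rid in targets:
        j = index[rid]
        e = np.zeros(len(model.reactions))
        e[j] = 1.0
        endpoints = []
        for maximize in (False, True):
            res = _solve(e, S, bounds, A_ub=A_ub, b_ub=b_ub, maximize=maximize)
            if res.status == 3:  # only possible with infinite box bounds
                endpoints.append(bounds[j][1] if maximize else bounds[j][0])
            elif res.status != 0:
                raise RuntimeError(f"FVA solve failed for {rid}: {res.message}")
            else:
                endpoints.append(float(res.x[j]))
        lo, hi = min(endpoints), max(endpoints)
        # clip solver noise into the reaction's own box
        lo, hi = max(lo, bounds[j][0]), min(hi, bounds[j][1])
        intervals[rid] = (lo, hi)
        bounded[rid] = (
            lo - bounds[j][0] > REPORT_TOL,
            bounds[j][1] - hi > REPORT_TOL,
        )
    return FVAResult(fraction=fraction, intervals=intervals, bounded=bounded)


Interval = Tuple[float, float]


def normalize_to_reference(
    values: Mapping[str, Union[float, Interval]],
    reference: Union[str, float],
) -> Dict[str, Union[float, Interval]]:
    """Express fluxes (or flux intervals) as percent of a reference flux.

    ``reference`` is either a number (the reference flux, e.g. the glucose
    uptake rate) or a key of ``values``.  Each entry is multiplied by
    100/|reference|; interval endpoints map independently with order
    preserved, so a consumption reference (negative flux) behaves the same
    as its magnitude.
    """
    if isinstance(reference, str):
        ref_value = values[reference]
        if isinstance(ref_value, tuple):
            ref = max(abs(ref_value[0]), abs(ref_value[1]))
        else:
            ref = float(ref_value)
    else:
        ref = float(reference)
    if abs(ref) <= 0:
        raise ValueError("reference flux magnitude must be positive")
    scale = 100.0 / abs(ref)
    out: Dict[str, Union[float, Interval]] = {}
    for key, val in values.items():
        if isinstance(val, tuple):
            a, b = val[0] * scale, val[1] * scale
            out[key] = (min(a, b), max(a, b))
        else:
            out[key] = val * scale
    return out


def interval_contains(
    fva_result: FVAResult, reaction_id: str, value: float, tol: float = REPORT_TOL
) -> bool:
    """Whether a measured flux falls inside the FVA interval (with slack).

    This is the containment check used to confront 13C-measured fluxes with
    (sub)optimal FVA ranges.
    """
    lo, hi = fva_result.intervals[reaction_id]
    return lo - tol <= value <= hi + tol
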