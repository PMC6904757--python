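"""Deterministic synthetic fixtures with known answers.

Everything here is a pure function of its arguments (seeded RNG, no global
state).  The toy networks have hand-derivable LP optima; the random
generator plants a feasible flux circulation so every network is viable by
construction; the batch simulator is the exact closed-form inverse of the
per-interval growth-rate / uptake-rate estimators; and the brute-force
vertex enumerator is an LP oracle independent of any solver, for networks
small enough to enumerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Dict, List, Sequence

import numpy as np

from .kinetics import BatchTimeCourse
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, build_stoich_matrix
from .gpr import parse_gpr

__all__ = [
    "PlantedNetwork",
    "make_toy_core",
    "make_branched_toy",
    "make_futile_cycle_toy",
    "make_dose_toy",
    "random_viable_network",
    "simulate_batch",
    "brute_force_lp_oracle",
]


@dataclass
class PlantedNetwork:
    """A random model plus a feasible flux vector proving its viability.

    The planted objective value is a lower bound on the true LP optimum
    (equal when no random side reaction opens a better route).
    """

    model: MetabolicModel
    planted_fluxes: Dict[str, float]
    planted_objective: float
    seed: int


def make_toy_core() -> MetabolicModel:
    """Minimal growth network: uptake -> transport -> doubling -> biomass drain.

    EX_A admits up to 10 units of A; T_A (gated by gene g1) internalizes it;
    R1 (gated by the complex g2+g3 or the isozyme g4) converts each A_c into
    two B_c; GROWTH drains B_c and is the objective.  Hand LP: uptake 10 ->
    10 through T_A and R1 -> 20 B_c -> optimum Z = 20.
    """
    return MetabolicModel(
        id="toy_core",
        metabolites=[
            Metabolite("A_e", name="substrate A (extracellular)", compartment="e", formula="C6H12O6"),
            Metabolite("A_c", name="substrate A", compartment="c", formula="C6H12O6"),
            Metabolite("B_c", name="biomass precursor B", compartment="c", formula="C3H6O3"),
        ],
        reactions=[
            Reaction("EX_A", {"A_e": -1.0}, lower_bound=-10.0, upper_bound=DEFAULT_BOUND,
                     name="A exchange"),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lower_bound=0.0,
                     upper_bound=DEFAULT_BOUND, name="A transport", gpr=parse_gpr("g1")),
            Reaction("R1", {"A_c": -1.0, "B_c": 2.0}, lower_bound=0.0,
                     upper_bound=DEFAULT_BOUND, name="A to 2 B",
                     gpr=parse_gpr("(g2 and g3) or g4")),
            Reaction("GROWTH", {"B_c": -1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                     name="biomass drain"),
        ],
        genes=["g1", "g2", "g3", "g4"],
        objective={"GROWTH": 1.0},
    )


def make_branched_toy() -> MetabolicModel:
    """Toy core plus a product branch competing with growth for carbon.

    Adds P_c, the branch R2: A_c -> P_c, and the product exchange EX_P.
    Hand LP at uptake 10: max growth 20 (all carbon through R1).  Holding
    growth at a fraction f of 20 leaves (1-f)*10 units of A_c for the
    branch, so the two-stage production optimum is 0 at f=1.0, 1.0 at
    f=0.9 and 5.0 at f=0.5.
    """
    model = make_toy_core()
    model.id = "branched_toy"
    model.metabolites.append(Metabolite("P_c", name="product P", compartment="c"))
    model.reactions.append(
        Reaction("R2", {"A_c": -1.0, "P_c": 1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                 name="A to product P", gpr=parse_gpr("g5"))
    )
    model.reactions.append(
        Reaction("EX_P", {"P_c": -1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                 name="P drain")
    )
    model.genes.append("g5")
    return model


def make_futile_cycle_toy() -> MetabolicModel:
    """Toy core plus a two-reaction futile cycle A_c <-> M_c.

    The cycle carries no net conversion, so the FBA optimum is unchanged,
    its FVA interval spans the +/-1000 box at any fraction, and total-flux
    minimization zeroes it out.
    """
    model = make_toy_core()
    model.id = "futile_cycle_toy"
    model.metabolites.append(Metabolite("M_c", name="cycle metabolite", compartment="c"))
    for rid in ("CYC_F", "CYC_R"):
        model.reactions.append(
            Reaction(rid, {"A_c": -1.0, "M_c": 1.0} if rid == "CYC_F" else {"M_c": -1.0, "A_c": 1.0},
                     lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND)
        )
    return model


def make_dose_toy(assimilating: bool = False, sink_capacity: float = DEFAULT_BOUND) -> MetabolicModel:
    """Toy core plus a dosed compound F for forced-uptake scans.

    F enters through EX_F and leaves through an excretion boundary SINK_F
    (capacity ``sink_capacity``).  Without an assimilation route the biomass
    optimum is flat in the dose (the compound is simply passed through, the
    signature of a strain that cannot co-metabolize it); with
    ``assimilating=True`` an F -> biomass-precursor reaction is added and the
    optimum rises with the dose.  Doses beyond ``sink_capacity`` in the
    non-assimilating toy are infeasible.
    """
    model = make_toy_core()
    model.id = "dose_toy_assimilating" if assimilating else "dose_toy"
    model.metabolites.append(Metabolite("F_e", name="dosed compound F", compartment="e",
                                        formula="CH2O"))
    model.reactions.append(
        Reaction("EX_F", {"F_e": -1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                 name="F exchange")
    )
    model.reactions.append(
        Reaction("SINK_F", {"F_e": -1.0}, lower_bound=0.0, upper_bound=sink_capacity,
                 name="F excretion")
    )
    if assimilating:
        model.reactions.append(
            Reaction("ASSIM_F", {"F_e": -1.0, "B_c": 1.0}, lower_bound=0.0,
                     upper_bound=DEFAULT_BOUND, name="F assimilation")
        )
    return model


def random_viable_network(
    n_metabolites: int = 5, n_reactions: int = 7, seed: int = 0
) -> PlantedNetwork:
    """Random sparse network with a planted feasible circulation.

    A backbone (uptake exchange -> linear conversion chain -> objective
    drain) carries a planted flux f drawn from the RNG, guaranteeing
    feasibility and a positive objective; the remaining reactions get random
    sparse stoichiometry with zero planted flux and bounds containing 0.
    Fully deterministic per seed.
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    if n_reactions < n_metabolites:
        raise ValueError("need n_reactions >= n_metabolites")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"M{i + 1}", compartment="c") for i in range(n_metabolites)]
    mets[0] = Metabolite("M1", compartment="e")
    f = float(np.round(rng.uniform(1.0, 10.0), 3))

    # backbone: EX_in on M1, chain M1 -> ... -> M_{m-1}, drain on M_{m-1}
    chain_len = n_metabolites - 2  # conversions between the first m-1 metabolites
    reactions = [Reaction("EX_in", {"M1": -1.0}, lower_bound=-f, upper_bound=DEFAULT_BOUND)]
    planted = {"EX_in": -f}
    for k in range(chain_len):
        rid = f"C{k + 1}"
        reactions.append(
            Reaction(rid, {f"M{k + 1}": -1.0, f"M{k + 2}": 1.0},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        )
        planted[rid] = f
    drain_met = f"M{max(n_metabolites - 1, 1)}"
    reactions.append(Reaction("DRAIN", {drain_met: -1.0}, lower_bound=0.0,
                              upper_bound=DEFAULT_BOUND))
    planted["DRAIN"] = f

    met_ids = [m.id for m in mets]
    for extra in range(n_reactions - len(reactions)):
        rid = f"X{extra + 1}"
        size = int(rng.integers(2, min(4, n_metabolites) + 1))
        chosen = rng.choice(met_ids, size=size, replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=size)
        if np.all(coeffs > 0):
            coeffs[0] = -coeffs[0]
        if np.all(coeffs < 0):
            coeffs[-1] = -coeffs[-1]
        lb = -float(np.round(rng.uniform(1.0, 20.0), 3)) if rng.random() < 0.5 else 0.0
        ub = float(np.round(rng.uniform(1.0, 20.0), 3))
        reactions.append(
            Reaction(rid, {m: float(c) for m, c in zip(chosen, coeffs)},
                     lower_bound=lb, upper_bound=ub)
        )
        planted[rid] = 0.0

    model = MetabolicModel(
        id=f"planted_seed{seed}",
        metabolites=mets,
        reactions=reactions,
        objective={"DRAIN": 1.0},
    )
    model.validate()
    S = build_stoich_matrix(model)
    v = np.array([planted[r.id] for r in model.reactions])
    assert np.max(np.abs(S @ v)) < 1e-9, "planted circulation must satisfy steady state"
    return PlantedNetwork(model=model, planted_fluxes=planted, planted_objective=f, seed=seed)


def simulate_batch(
    mu: float,
    v_substrate: float,
    x0: float,
    C0: float,
    times: Sequence[float],
) -> BatchTimeCourse:
    """Closed-form batch culture: exponential biomass, consistent substrate.

    x(t) = x0 exp(mu t); over each interval the substrate changes by
    C_{i+1} = C_i + v x_i (exp(mu dt_i) - 1) / mu, which is exactly the
    trajectory whose per-interval estimators recover (mu, v).  ``v_substrate``
    is signed (negative = consumption).  Raises if the substrate would go
    negative.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    times = np.asarray(times, dtype=float)
    x = x0 * np.exp(mu * times)
    C = np.empty_like(x)
    C[0] = C0
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        C[i + 1] = C[i] + v_substrate * x[i] * (math.exp(mu * dt) - 1.0) / mu
    if np.any(C < 0):
        raise ValueError("substrate becomes negative; increase C0 or shorten the course")
    return BatchTimeCourse(times=times, biomass=x, substrate=C)


def brute_force_lp_oracle(model: MetabolicModel, tol: float = 1e-7) -> float:
    """Max objective by exhaustive vertex enumeration; test oracle only.

    The feasible set {v : S v = 0, lb <= v <= ub} is a bounded polytope when
    all bounds are finite; each vertex activates enough bound constraints to
    pin v given the steady-state rows.  All choices of (reaction, bound
    side) are enumerated, singular systems skipped, infeasible points
    filtered, and the best objective returned.  Exponential in the nullspace
    dimension — restricted to <= 10 reactions.
    """
    n = len(model.reactions)
    if n == 0:
        return 0.0
    if n > 10:
        raise ValueError("oracle is exponential; use <= 10 reactions")
    S = build_stoich_matrix(model).toarray()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle requires finite bounds")
    c = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        c[j] = model.objective.get(rxn.id, 0.0)
    d = n - np.linalg.matrix_rank(S) if S.size else n
    best = None
    for combo in combinations(range(n), d):
        for sides in product((0, 1), repeat=d):
            rows = [S] if S.size else []
            rhs = [np.zeros(S.shape[0])] if S.size else []
            for j, side in zip(combo, sides):
                e = np.zeros(n)
                e[j] = 1.0
                rows.append(e[None, :])
                rhs.append(np.array([ub[j] if side else lb[j]]))
            A = np.vstack(rows)
            b = np.concatenate(rhs)
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    if best is None:
        raise ValueError("no feasible vertex found; model is infeasible")
    return best
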