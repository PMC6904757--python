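"""FBA, min-total-flux, FVA and the supporting interval utilities."""

import numpy as np
import pytest

from megaflux import (
    apply_medium,
    brute_force_lp_oracle,
    build_stoich_matrix,
    fva,
    interval_contains,
    min_total_flux,
    normalize_to_reference,
    random_viable_network,
    solve_fba,
)
from megaflux.lp import FVAResult


class TestFBA:
    def test_toy_optimum_matches_hand_lp(self, toy_core):
        result = solve_fba(apply_medium(toy_core, {"EX_A": 10.0}))
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(20.0, abs=1e-6)

    def test_starvation_gives_zero(self, toy_core):
        result = solve_fba(apply_medium(toy_core, {}))
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_respected(self, branched_toy):
        result = solve_fba(branched_toy)
        assert result.steady_state_residual(branched_toy) <= 1e-6
        for rxn in branched_toy.reactions:
            v = result.fluxes[rxn.id]
            assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9

    def test_infeasible_is_status_not_exception(self, toy_core):
        broken = toy_core.copy()
        ex = broken.reaction("EX_A")
        ex.lower_bound = ex.upper_bound = -10.0  # forced uptake
        t = broken.reaction("T_A")
        t.lower_bound = t.upper_bound = 0.0  # nowhere for A to go
        result = solve_fba(broken)
        assert result.status == "infeasible"
        assert result.fluxes == {}

    def test_empty_objective_raises(self, toy_core):
        stripped = toy_core.copy()
        stripped.objective = {}
        with pytest.raises(ValueError, match="objective"):
            solve_fba(stripped)

    def test_planted_network_meets_planted_objective(self):
        planted = random_viable_network(5, 7, seed=1)
        result = solve_fba(planted.model)
        assert result.status == "optimal"
        assert result.objective_value >= planted.planted_objective - 1e-9


@pytest.mark.parametrize("seed", range(50))
def test_fba_matches_vertex_enumeration_oracle(seed):
    """On small random networks the LP optimum equals exhaustive vertex search."""
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, 6))
    n_rxns = int(rng.integers(n_mets, 9))
    planted = random_viable_network(n_mets, n_rxns, seed=seed)
    lp_value = solve_fba(planted.model).objective_value
    oracle_value = brute_force_lp_oracle(planted.model)
    assert lp_value == pytest.approx(oracle_value, abs=1e-6)


class TestMinTotalFlux:
    def test_unique_distribution_equals_fba(self, linear_chain):
        fba_fluxes = solve_fba(linear_chain).fluxes
        parsimonious = min_total_flux(linear_chain)
        for rid, v in fba_fluxes.items():
            assert parsimonious[rid] == pytest.approx(v, abs=1e-6)

    def test_futile_cycle_carries_no_flux(self, futile_toy):
        fluxes = min_total_flux(futile_toy)
        assert fluxes["CYC_F"] == pytest.approx(0.0, abs=1e-6)
        assert fluxes["CYC_R"] == pytest.approx(0.0, abs=1e-6)

    def test_cycle_changes_neither_optimum_nor_total_flux(self, toy_core, futile_toy):
        assert solve_fba(futile_toy).objective_value == pytest.approx(
            solve_fba(toy_core).objective_value, abs=1e-9)
        total = lambda fluxes: sum(abs(v) for v in fluxes.values())
        assert total(min_total_flux(futile_toy)) <= total(min_total_flux(toy_core)) + 1e-6

    def test_relaxing_the_objective_cannot_raise_total_flux(self, toy_core):
        total = lambda fluxes: sum(abs(v) for v in fluxes.values())
        assert total(min_total_flux(toy_core, 0.9)) <= total(
            min_total_flux(toy_core, 1.0)) + 1e-9

    def test_objective_floor_is_met(self, branched_toy):
        z_star = solve_fba(branched_toy).objective_value
        for fraction in (1.0, 0.9, 0.5):
            fluxes = min_total_flux(branched_toy, fraction)
            achieved = sum(branched_toy.objective.get(rid, 0) * v
                           for rid, v in fluxes.items())
            assert achieved >= fraction * z_star - 1e-6

    def test_steady_state_holds(self, branched_toy):
        fluxes = min_total_flux(branched_toy, 0.9)
        S = build_stoich_matrix(branched_toy)
        v = np.array([fluxes[r.id] for r in branched_toy.reactions])
        assert np.max(np.abs(S @ v)) <= 1e-6

    def test_fraction_validation(self, toy_core):
        with pytest.raises(ValueError):
            min_total_flux(toy_core, 0.0)


class TestFVA:
    def test_linear_chain_intervals_degenerate_at_optimum(self, linear_chain):
        result = fva(linear_chain, fraction=1.0)
        fluxes = solve_fba(linear_chain).fluxes
        for rid, (lo, hi) in result.intervals.items():
            assert lo == pytest.approx(hi, abs=1e-6)
            assert lo == pytest.approx(fluxes[rid], abs=1e-6)

    def test_parallel_paths_share_the_span(self, parallel_paths):
        result = fva(parallel_paths, fraction=1.0)
        for rid in ("R1", "R1b"):
            lo, hi = result.intervals[rid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_suboptimal_intervals_contain_optimal_ones(self, branched_toy):
        tight = fva(branched_toy, fraction=1.0)
        loose = fva(branched_toy, fraction=0.9)
        for rid in tight.intervals:
            assert loose.intervals[rid][0] <= tight.intervals[rid][0] + 1e-6
            assert loose.intervals[rid][1] >= tight.intervals[rid][1] - 1e-6

    def test_optimal_distribution_lies_inside_intervals(self, branched_toy):
        fluxes = solve_fba(branched_toy).fluxes
        result = fva(branched_toy, fraction=1.0)
        for rid, v in fluxes.items():
            assert interval_contains(result, rid, v, tol=1e-6)

    def test_futile_cycle_flagged_unbounded(self, futile_toy):
        result = fva(futile_toy, fraction=1.0)
        lo, hi = result.intervals["CYC_F"]
        # the cycle spans the +/-1000 box: network does not constrain it
        assert lo == pytest.approx(-1000.0) and hi == pytest.approx(1000.0)
        assert result.bounded["CYC_F"] == (False, False)
        assert result.bounded["GROWTH"][1] is True

    def test_intervals_stay_within_reaction_bounds(self, futile_toy):
        result = fva(futile_toy, fraction=0.9)
        for rxn in futile_toy.reactions:
            lo, hi = result.intervals[rxn.id]
            assert rxn.lower_bound - 1e-9 <= lo <= hi <= rxn.upper_bound + 1e-9


class TestNormalization:
    def test_percent_of_uptake(self):
        values = {"EX_glc": -1.52, "PGI": 1.52, "ZERO": 0.0}
        scaled = normalize_to_reference(values, reference=1.52)
        assert scaled["PGI"] == pytest.approx(100.0)
        assert scaled["EX_glc"] == pytest.approx(-100.0)
        assert scaled["ZERO"] == 0.0

    def test_reference_by_key_and_interval_order(self):
        values = {"EX_glc": (-1.52, -1.52), "PGI": (0.76, 1.52)}
        scaled = normalize_to_reference(values, reference="EX_glc")
        assert scaled["PGI"] == pytest.approx((50.0, 100.0))
        lo, hi = scaled["EX_glc"]
        assert lo <= hi

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference({"a": 1.0}, reference=0.0)


@pytest.mark.parametrize(
    "interval,value,expected",
    [((0.0, 100.0), 42.0, True), ((5.0, 5.0), 5.0, True), ((0.0, 1.0), 2.0, False)],
)
def test_interval_containment(interval, value, expected):
    result = FVAResult(fraction=0.9, intervals={"R": interval})
    assert interval_contains(result, "R", value) is expected
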