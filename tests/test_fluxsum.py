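"""Flux-sum turnover: the half-sum identity and carbon-basis profiles."""

import numpy as np
import pytest

from megaflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    build_stoich_matrix,
    compute_flux_sum,
    flux_sum_profile,
    make_futile_cycle_toy,
    min_total_flux,
    normalize_rows,
    random_viable_network,
    solve_fba,
)
from megaflux.fluxsum import FluxSumProfile
import pandas as pd


def test_chain_intermediate_turns_over_at_the_chain_flux(linear_chain):
    fluxes = min_total_flux(linear_chain)
    phi = compute_flux_sum(linear_chain, fluxes)
    assert phi["B_c"] == pytest.approx(1.0, abs=1e-6)  # 1/2 (1 in + 1 out)
    assert phi["C_c"] == pytest.approx(1.0, abs=1e-6)


def test_stoichiometric_doubling_counts_in_phi(toy_core):
    # R1 makes 2 B per A at flux 10; growth drains 20 -> phi_B = 1/2(20+20)
    phi = compute_flux_sum(toy_core, min_total_flux(toy_core))
    assert phi["B_c"] == pytest.approx(20.0, abs=1e-6)
    assert phi["A_c"] == pytest.approx(10.0, abs=1e-6)


def test_zero_distribution_gives_zero_phi(toy_core):
    phi = compute_flux_sum(toy_core, {r.id: 0.0 for r in toy_core.reactions})
    assert all(v == 0.0 for v in phi.values.values())


def test_non_steady_distribution_rejected(toy_core):
    unbalanced = {r.id: 0.0 for r in toy_core.reactions}
    unbalanced["R1"] = 1.0
    with pytest.raises(ValueError, match="steady state"):
        compute_flux_sum(toy_core, unbalanced)


@pytest.mark.parametrize("seed", [0, 3, 11])
def test_conservation_identity_production_equals_consumption(seed):
    """phi equals both total production and total consumption of each metabolite."""
    model = random_viable_network(4, 7, seed=seed).model
    fluxes = min_total_flux(model)
    phi = compute_flux_sum(model, fluxes)
    S = build_stoich_matrix(model).toarray()
    v = np.array([fluxes[r.id] for r in model.reactions])
    rates = S * v  # met x rxn contribution matrix
    for i, met in enumerate(model.metabolites):
        production = rates[i][rates[i] > 0].sum()
        consumption = -rates[i][rates[i] < 0].sum()
        assert production == pytest.approx(consumption, abs=1e-6)
        assert phi[met.id] == pytest.approx(production, abs=1e-6)


def test_phi_scales_linearly_with_uptake(linear_chain):
    phi1 = compute_flux_sum(linear_chain, min_total_flux(linear_chain))
    doubled = linear_chain.copy()
    doubled.reaction("EX_A").lower_bound = -2.0
    phi2 = compute_flux_sum(doubled, min_total_flux(doubled))
    for met in ("B_c", "C_c"):
        assert phi2[met] == pytest.approx(2 * phi1[met], abs=1e-6)


def _two_source_model() -> MetabolicModel:
    """Two interchangeable 6-carbon sources feeding one biomass drain."""
    return MetabolicModel(
        id="two_sources",
        metabolites=[
            Metabolite("S1_e", compartment="e", formula="C6H12O6"),
            Metabolite("S2_e", compartment="e", formula="C6H12O6"),
            Metabolite("B_c", compartment="c"),
        ],
        reactions=[
            Reaction("EX_S1", {"S1_e": -1.0}, lower_bound=0.0),
            Reaction("EX_S2", {"S2_e": -1.0}, lower_bound=0.0),
            Reaction("A1", {"S1_e": -1.0, "B_c": 1.0}),
            Reaction("A2", {"S2_e": -1.0, "B_c": 1.0}),
            Reaction("GROWTH", {"B_c": -1.0}),
        ],
        objective={"GROWTH": 1.0},
    )


class TestProfile:
    def test_carbon_basis_sets_uptake_to_basis_over_carbons(self):
        model = _two_source_model()
        profile = flux_sum_profile(model, {}, ["EX_S1"], carbon_basis=1.0)
        # 6-carbon source at 1 mmol carbon basis -> uptake 1/6 -> growth 1/6
        assert profile.table.loc["B_c", "EX_S1"] == pytest.approx(1 / 6, abs=1e-6)

    def test_interchangeable_sources_give_identical_columns(self):
        model = _two_source_model()
        profile = flux_sum_profile(model, {}, ["EX_S1", "EX_S2"], carbon_basis=1.0)
        col1 = profile.table["EX_S1"].to_numpy()
        col2 = profile.table["EX_S2"].to_numpy()
        # the source species differ but the shared pathway turnover matches
        assert profile.table.loc["B_c", "EX_S1"] == pytest.approx(
            profile.table.loc["B_c", "EX_S2"], abs=1e-6)
        assert np.sort(col1) == pytest.approx(np.sort(col2), abs=1e-6)

    def test_unknown_carbon_count_is_an_error(self):
        model = _two_source_model()
        model.metabolite("S1_e").formula = ""
        with pytest.raises(ValueError, match="S1_e"):
            flux_sum_profile(model, {}, ["EX_S1"])

    def test_carbon_count_table_fallback(self):
        model = _two_source_model()
        model.metabolite("S1_e").formula = ""
        profile = flux_sum_profile(model, {}, ["EX_S1"], carbon_counts={"S1_e": 6})
        assert profile.table.loc["B_c", "EX_S1"] == pytest.approx(1 / 6, abs=1e-6)


class TestNormalizeRows:
    def test_rows_divided_by_max(self):
        table = pd.DataFrame({"a": [2.0, 0.0], "b": [4.0, 0.0], "c": [1.0, 0.0]},
                             index=["m1", "m2"])
        normalized = normalize_rows(FluxSumProfile(table=table)).table
        assert list(normalized.loc["m1"]) == pytest.approx([0.5, 1.0, 0.25])
        assert list(normalized.loc["m2"]) == [0.0, 0.0, 0.0]  # all-zero row stays

    def test_single_column_profile_is_all_ones_or_zero(self):
        table = pd.DataFrame({"only": [3.0, 0.0]}, index=["m1", "m2"])
        normalized = normalize_rows(FluxSumProfile(table=table)).table
        assert list(normalized["only"]) == [1.0, 0.0]

    def test_idempotent(self):
        table = pd.DataFrame({"a": [2.0], "b": [8.0]}, index=["m1"])
        once = normalize_rows(FluxSumProfile(table=table))
        twice = normalize_rows(once)
        pd.testing.assert_frame_equal(once.table, twice.table)
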