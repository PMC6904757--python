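"""Model domain operations: knockouts, media, transporters, S matrix, stats."""

from itertools import chain, combinations

import numpy as np
import pytest

from megaflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    add_hypothetical_transporter,
    apply_medium,
    build_stoich_matrix,
    carbon_count,
    knockout_genes,
    knockout_reactions,
    model_stats,
    solve_fba,
)


class TestKnockouts:
    def test_single_gene_closes_gated_reaction(self, toy_core):
        ko = knockout_genes(toy_core, {"g1"})
        assert ko.reaction("T_A").lower_bound == 0
        assert ko.reaction("T_A").upper_bound == 0
        assert solve_fba(ko).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_empty_knockout_is_identity(self, toy_core):
        ko = knockout_genes(toy_core, set())
        for before, after in zip(toy_core.reactions, ko.reactions):
            assert (before.lower_bound, before.upper_bound) == (
                after.lower_bound, after.upper_bound)

    def test_isozyme_survives_partial_or_knockout(self, toy_core):
        ko = knockout_genes(toy_core, {"g2"})  # R1 gated by (g2 and g3) or g4
        r1 = ko.reaction("R1")
        assert (r1.lower_bound, r1.upper_bound) == (0.0, 1000.0)
        assert solve_fba(ko).objective_value == pytest.approx(20.0, abs=1e-6)

    def test_unknown_gene_raises(self, toy_core):
        with pytest.raises(KeyError):
            knockout_genes(toy_core, {"nope"})

    def test_knockout_never_mutates_input(self, toy_core):
        knockout_genes(toy_core, {"g1"})
        assert toy_core.reaction("T_A").upper_bound == 1000.0

    def test_reaction_knockout_closes_listed(self, toy_core):
        ko = knockout_reactions(toy_core, {"R1"})
        assert ko.reaction("R1").upper_bound == 0
        assert solve_fba(ko).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_reaction_knockout_empty_identity(self, toy_core):
        ko = knockout_reactions(toy_core, set())
        assert solve_fba(ko).objective_value == pytest.approx(20.0, abs=1e-6)

    def test_knockout_monotonicity(self, toy_core):
        """Deleting genes can only lower the growth optimum."""
        base = solve_fba(toy_core).objective_value
        genes = toy_core.genes
        for subset in chain.from_iterable(
            combinations(genes, k) for k in range(len(genes) + 1)
        ):
            after = solve_fba(knockout_genes(toy_core, set(subset))).objective_value
            assert after <= base + 1e-9


class TestMedium:
    def test_paper_style_glucose_bound(self, toy_core):
        conditioned = apply_medium(toy_core, {"EX_A": 1.52})
        assert conditioned.reaction("EX_A").lower_bound == pytest.approx(-1.52)

    def test_empty_medium_starves(self, toy_core):
        conditioned = apply_medium(toy_core, {})
        assert all(r.lower_bound == 0 for r in conditioned.exchange_reactions())
        assert solve_fba(conditioned).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_hand_lp_growth_value(self, toy_core):
        conditioned = apply_medium(toy_core, {"EX_A": 10.0})
        assert solve_fba(conditioned).objective_value == pytest.approx(20.0, abs=1e-6)

    def test_idempotent(self, toy_core):
        once = apply_medium(toy_core, {"EX_A": 3.0})
        twice = apply_medium(once, {"EX_A": 3.0})
        for a, b in zip(once.reactions, twice.reactions):
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)

    def test_non_exchange_key_rejected(self, toy_core):
        with pytest.raises(KeyError):
            apply_medium(toy_core, {"R1": 5.0})

    def test_negative_uptake_rejected(self, toy_core):
        with pytest.raises(ValueError):
            apply_medium(toy_core, {"EX_A": -1.0})

    def test_secretion_bounds_untouched(self, toy_core):
        conditioned = apply_medium(toy_core, {})
        assert conditioned.reaction("EX_A").upper_bound == 1000.0


class TestHypotheticalTransporter:
    def test_adds_twin_transport_and_exchange(self, toy_core):
        extended = add_hypothetical_transporter(toy_core, "B_c")
        assert extended.has_metabolite("B_e")
        assert extended.has_reaction("T_B")
        assert extended.has_reaction("EX_B_e")
        assert extended.hypothetical == {"T_B", "EX_B_e"}
        assert extended.reaction("T_B").gpr.is_empty
        # growth on B alone becomes feasible
        fed = apply_medium(extended, {"EX_B_e": 10.0})
        assert solve_fba(fed).objective_value == pytest.approx(10.0, abs=1e-6)

    def test_double_add_rejected(self, toy_core):
        extended = add_hypothetical_transporter(toy_core, "B_c")
        with pytest.raises(ValueError, match="already exists"):
            add_hypothetical_transporter(extended, "B_c")

    def test_original_model_untouched(self, toy_core):
        add_hypothetical_transporter(toy_core, "B_c")
        assert not toy_core.has_reaction("T_B")

    def test_extracellular_metabolite_rejected(self, toy_core):
        with pytest.raises(ValueError, match="extracellular"):
            add_hypothetical_transporter(toy_core, "A_e")


class TestStoichMatrix:
    def test_toy_core_shape_and_exchange_column(self, toy_core):
        S = build_stoich_matrix(toy_core)
        assert S.shape == (3, 4)
        col = S[:, 0].toarray().ravel()  # EX_A
        assert col[0] == -1 and np.count_nonzero(col) == 1

    def test_empty_model(self):
        S = build_stoich_matrix(MetabolicModel(id="empty"))
        assert S.shape == (0, 0)

    def test_columns_round_trip_stoichiometry(self, branched_toy):
        S = build_stoich_matrix(branched_toy).toarray()
        met_index = {m.id: i for i, m in enumerate(branched_toy.metabolites)}
        for j, rxn in enumerate(branched_toy.reactions):
            rebuilt = {
                mid: S[i, j] for mid, i in met_index.items() if S[i, j] != 0
            }
            assert rebuilt == rxn.stoichiometry


class TestStats:
    def test_toy_core_counts(self, toy_core):
        stats = model_stats(toy_core)
        assert stats["n_reactions"] == 4
        assert stats["n_metabolites"] == 3
        assert stats["n_genes"] == 4
        # EX_A and the single-metabolite biomass drain are boundary reactions
        assert stats["n_exchange"] == 2
        assert stats["pct_gene_associated_excluding_exchange"] == 100

    def test_percentage_excludes_exchanges(self, branched_toy):
        stats = model_stats(branched_toy)
        # internal: T_A, R1, R2 all gene-associated
        assert stats["pct_gene_associated_excluding_exchange"] == 100
        assert stats["n_exchange"] == 3


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C6H12O6", 6),
        ("CH2O", 1),
        ("H2O", 0),
        ("CaCl2", 0),  # Ca/Cl are not carbon
        ("C15H28O2", 15),
        ("", None),
        ("not-a-formula", None),
    ],
)
def test_carbon_count(formula, expected):
    assert carbon_count(formula) == expected


def test_validation_catches_dangling_references(toy_core):
    from megaflux import ModelValidationError

    broken = toy_core.copy()
    broken.reactions[0].stoichiometry = {"ghost": -1.0}
    with pytest.raises(ModelValidationError, match="ghost"):
        broken.validate()
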