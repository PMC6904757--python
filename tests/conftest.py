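import pytest

from megaflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    make_branched_toy,
    make_dose_toy,
    make_futile_cycle_toy,
    make_toy_core,
)


@pytest.fixture
def toy_core() -> MetabolicModel:
    return make_toy_core()


@pytest.fixture
def branched_toy() -> MetabolicModel:
    return make_branched_toy()


@pytest.fixture
def futile_toy() -> MetabolicModel:
    return make_futile_cycle_toy()


@pytest.fixture
def linear_chain() -> MetabolicModel:
    """A -> B -> C straight line at capped uptake 1; unique flux distribution."""
    return MetabolicModel(
        id="linear_chain",
        metabolites=[
            Metabolite("A_e", compartment="e"),
            Metabolite("B_c", compartment="c"),
            Metabolite("C_c", compartment="c"),
        ],
        reactions=[
            Reaction("EX_A", {"A_e": -1.0}, lower_bound=-1.0),
            Reaction("R_AB", {"A_e": -1.0, "B_c": 1.0}),
            Reaction("R_BC", {"B_c": -1.0, "C_c": 1.0}),
            Reaction("DRAIN_C", {"C_c": -1.0}),
        ],
        objective={"DRAIN_C": 1.0},
    )


@pytest.fixture
def parallel_paths(toy_core) -> MetabolicModel:
    """Toy core with a duplicate of R1: two equivalent routes share the flux."""
    model = toy_core.copy()
    model.id = "parallel_paths"
    r1 = model.reaction("R1")
    model.reactions.append(
        Reaction("R1b", dict(r1.stoichiometry), lower_bound=r1.lower_bound,
                 upper_bound=r1.upper_bound)
    )
    return model


@pytest.fixture
def dose_toy() -> MetabolicModel:
    return make_dose_toy(assimilating=False)


@pytest.fixture
def dose_toy_assimilating() -> MetabolicModel:
    return make_dose_toy(assimilating=True)
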