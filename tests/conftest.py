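import numpy as np
import pytest

from statevar.metabolic_model import (
    CONTROL,
    STRESSED,
    MetaboliteSpec,
    MetabolicModel,
    ReactionSpec,
)
from statevar.synthetic_data import make_ladder_network, make_metabolic_fixture


@pytest.fixture(scope="session")
def fig1_model():
    return make_metabolic_fixture()


@pytest.fixture(scope="session")
def ladder():
    return make_ladder_network()


def _two_species(v_ctrl=1.0, v_str=2.0, a0=2.0, b0=0.0):
    return MetabolicModel(
        metabolites=(
            MetaboliteSpec(id="A", initial_amount=a0, is_state_metabolite=True),
            MetaboliteSpec(id="B", initial_amount=b0, is_fitting_target=True),
        ),
        reactions=(
            ReactionSpec(
                id="R1",
                substrates=(("A", 1.0),),
                products=(("B", 1.0),),
                km={"A": 1.0},
                vmax_by_condition={CONTROL: v_ctrl, STRESSED: v_str},
            ),
        ),
    )


@pytest.fixture(scope="session")
def two_species_model():
    """Closed A -> B system: total amount conserved."""
    return _two_species()


@pytest.fixture(scope="session")
def small_model():
    """Fast 3-metabolite model with one state metabolite, distinct conditions."""
    return MetabolicModel(
        metabolites=(
            MetaboliteSpec(id="X", initial_amount=2.0, is_fitting_target=True),
            MetaboliteSpec(
                id="Y",
                initial_amount=0.5,
                is_fitting_target=True,
                is_state_metabolite=True,
            ),
            MetaboliteSpec(id="Z", initial_amount=0.2, is_fitting_target=True),
        ),
        reactions=(
            ReactionSpec(
                id="R1",
                substrates=(("X", 1.0),),
                products=(("Y", 1.0),),
                km={"X": 1.0},
                vmax_by_condition={CONTROL: 0.3, STRESSED: 3.0},
            ),
            ReactionSpec(
                id="R2",
                substrates=(("Y", 1.0),),
                products=(("Z", 1.0),),
                km={"Y": 0.5},
                vmax_by_condition={CONTROL: 0.3, STRESSED: 0.1},
            ),
            ReactionSpec(
                id="R3",
                substrates=(("Z", 1.0),),
                products=(),
                km={"Z": 0.2},
                vmax_by_condition={CONTROL: 0.3, STRESSED: 0.3},
            ),
        ),
    )
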