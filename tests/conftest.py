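import numpy as np
import pytest

from fluxshift import (
    ConditionSpec,
    MetabolicModel,
    build_condition_pair,
    toy_network,
)


@pytest.fixture
def toy():
    return toy_network()


@pytest.fixture
def toy_pair(toy):
    """Toy network with the g1 knockout condition (forces R_BC in WT)."""
    spec = ConditionSpec(
        name="ko_g1", perturbation_targets=["g1"], target_kind="genes"
    )
    return build_condition_pair(toy, spec)


@pytest.fixture
def chain_model():
    """Linear chain: import of A (written +1, capped at 5) -> A -> B -> export.

    The importer is deliberately written with a +1 stoichiometric
    coefficient to exercise the sign-flip convention; maximum export of B
    is limited by the import cap of 5, not the internal cap of 10.
    """
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["IMPORT_A", "R_AB", "EXPORT_B"],
        S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lb=np.array([0.0, 0.0, 0.0]),
        ub=np.array([5.0, 10.0, 1000.0]),
        name="chain",
    )


@pytest.fixture
def box_model():
    """1-D flux polytope: a single import/export pair with v in [0, 10]."""
    return MetabolicModel(
        metabolite_ids=["A"],
        reaction_ids=["EX_in", "EX_out"],
        S=np.array([[1.0, -1.0]]),
        lb=np.array([0.0, 0.0]),
        ub=np.array([10.0, 10.0]),
        name="box",
    )
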