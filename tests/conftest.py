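import numpy as np
import pytest

from adbphylo import (ADBParams, CompleteTree, SimConfig,
                      simulate_reconstructed_tree)


@pytest.fixture(scope="session")
def three_tip_newick():
    return "((A:1,B:1):1,C:2);"


@pytest.fixture(scope="session")
def bd_params():
    """k = 1 parameter set used for birth-death oracle comparisons."""
    return ADBParams(k=1, ell=1.0, d=0.2, rho=0.5)


@pytest.fixture(scope="session")
def bd_trees(bd_params):
    """Ten 20-tip reconstructed trees simulated at k = 1."""
    return [simulate_reconstructed_tree(SimConfig(params=bd_params, n_tips=20),
                                        seed=100 + i) for i in range(10)]


@pytest.fixture(scope="session")
def erlang_params():
    """The fixed parameter set of the tree-size simulation study."""
    return ADBParams(k=5, ell=10.0, d=0.1, rho=0.1)


@pytest.fixture(scope="session")
def erlang_tree20(erlang_params):
    return simulate_reconstructed_tree(
        SimConfig(params=erlang_params, n_tips=20), seed=42)


@pytest.fixture(scope="session")
def hand_complete_tree():
    """Complete tree with stem 10, one internal branch 12, one death
    branch 11 and two censored extant branches.

    Layout (backward times): origin 40, root division at 30, internal
    division at 18, death tip at 7, extant tips at 0.
    """
    #        40 (origin)
    #        30 root division
    #       /  \
    #     18    0 (extant)
    #    /  \
    #   7    0 (extant)
    # (death)
    parent = [-1, 0, 0, 1, 1]
    children = [(1, 2), (3, 4), (), (), ()]
    times = [30.0, 18.0, 0.0, 7.0, 0.0]
    events = ["division", "division", "extant", "death", "extant"]
    return CompleteTree(parent, children, times, events,
                        sampled=[False, False, True, False, True], t_or=40.0)
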