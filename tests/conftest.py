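"""Shared fixtures: tiny hand-built observed pairs and simulated ones.

The three-node path with forest {cherry(1,3), leaf 2} is the workhorse
fixture: its two compatible histories are mirror images with identical
probability 0.5 * p * (1 - p_c), so the exact likelihood is
p * (1 - p_c) and the particle filter reproduces it exactly for any
particle count and seed.
"""

import pytest

from dmcinfer import (DMCParams, DuplicationForest, PPIGraph, simulate_dmc)


@pytest.fixture
def params07():
    return DMCParams(p=0.7, p_c=0.7)


@pytest.fixture
def seed_pair():
    return PPIGraph.seed(), DuplicationForest.trivial()


@pytest.fixture
def path_pair():
    """Path 1-2-3 with forest cherry{1,3} + leaf 2."""
    return (PPIGraph(edges=[(1, 2), (2, 3)]),
            DuplicationForest([(1, 3), 2]))


@pytest.fixture
def triangle_pair():
    """Triangle on {1,2,3} with forest cherry{1,3} + leaf 2."""
    return (PPIGraph(edges=[(1, 2), (2, 3), (1, 3)]),
            DuplicationForest([(1, 3), 2]))


@pytest.fixture
def simulated_pair_factory(params07):
    """Simulate an observed (graph, forest) pair of a given size."""
    def factory(size, seed, params=None):
        history = simulate_dmc(params or params07, size, seed=seed)
        return history.final_graph, history.final_forest
    return factory
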