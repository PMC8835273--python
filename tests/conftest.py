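import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from parksocial.bbn import BeliefNetwork, ConditionalTable, NetworkStructure


def make_net(edges, states, cpts):
    """Build a BeliefNetwork from plain dicts (states: name -> tuple,
    cpts: name -> array-like shaped (*parent_cards, child_card))."""
    nodes = tuple(states)
    structure = NetworkStructure(nodes, tuple(edges))
    tables = {}
    for n in nodes:
        parents = structure.parents(n)
        tables[n] = ConditionalTable(
            n,
            tuple(states[n]),
            parents,
            tuple(tuple(states[p]) for p in parents),
            np.asarray(cpts[n], dtype=float),
        )
    return BeliefNetwork(structure, tables)


@pytest.fixture
def chain_net():
    """A -> B with P(A=a)=0.3, P(B=b|a)=0.9, P(B=b|a2)=0.2."""
    return make_net(
        edges=[("A", "B")],
        states={"A": ("a", "a2"), "B": ("b", "b2")},
        cpts={"A": [0.3, 0.7], "B": [[0.9, 0.1], [0.2, 0.8]]},
    )


@pytest.fixture
def copy_net():
    """Deterministic binary copy X -> Y of a fair coin."""
    return make_net(
        edges=[("X", "Y")],
        states={"X": ("h", "t"), "Y": ("h", "t")},
        cpts={"X": [0.5, 0.5], "Y": [[1.0, 0.0], [0.0, 1.0]]},
    )
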