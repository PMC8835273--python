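"""Independent brute-force oracles used to check the package's fast paths.

Everything here deliberately avoids the package's inference machinery:
joints are materialized as full dense arrays over every state combination,
the congregate index is evaluated with a plain scalar loop, and mutual
information is summed term by term from the enumerated joint.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from parksocial.bbn import BeliefNetwork, ConditionalTable, NetworkStructure


def full_joint(net: BeliefNetwork) -> tuple[list[str], np.ndarray]:
    """Dense joint array, one axis per node in ``net.nodes`` order."""
    nodes = list(net.nodes)
    cards = [net.card(n) for n in nodes]
    joint = np.ones(cards)
    for n in nodes:
        cpt = net.tables[n]
        # broadcast the CPT over the full joint shape
        axes = [nodes.index(p) for p in cpt.parents] + [nodes.index(n)]
        # order the CPT's axes to match ascending joint axes
        order = np.argsort(axes)
        arr = np.transpose(cpt.probs, order)
        shape_sorted = [1] * len(nodes)
        for a in axes:
            shape_sorted[a] = cards[a]
        joint = joint * arr.reshape(shape_sorted)
    return nodes, joint


def enum_posterior(net: BeliefNetwork, query: str, evidence: dict[str, str]) -> np.ndarray:
    nodes, joint = full_joint(net)
    idx: list[object] = [slice(None)] * len(nodes)
    for var, state in evidence.items():
        idx[nodes.index(var)] = net.state_index(var, state)
    sub = joint[tuple(idx)]
    keep_axis = [n for n in nodes if n not in evidence].index(query)
    axes = tuple(a for a in range(sub.ndim) if a != keep_axis)
    vec = sub.sum(axis=axes)
    return vec / vec.sum()


def enum_evidence_probability(net: BeliefNetwork, evidence: dict[str, str]) -> float:
    nodes, joint = full_joint(net)
    idx: list[object] = [slice(None)] * len(nodes)
    for var, state in evidence.items():
        idx[nodes.index(var)] = net.state_index(var, state)
    return float(np.asarray(joint[tuple(idx)]).sum())


def enum_mutual_information(net: BeliefNetwork, a: str, b: str) -> float:
    """MI in bits between two nodes, term-by-term from the enumerated joint."""
    nodes, joint = full_joint(net)
    ia, ib = nodes.index(a), nodes.index(b)
    axes = tuple(x for x in range(len(nodes)) if x not in (ia, ib))
    pab = joint.sum(axis=axes)
    if ia > ib:
        pab = pab.T
    pa = pab.sum(axis=1)
    pb = pab.sum(axis=0)
    mi = 0.0
    for i in range(pab.shape[0]):
        for j in range(pab.shape[1]):
            if pab[i, j] > 0:
                mi += pab[i, j] * math.log2(pab[i, j] / (pa[i] * pb[j]))
    return mi


def scalar_congregate_index(area_m2, a_start, a_end, persons) -> float:
    """Plain-loop evaluation of the congregate-index formula."""
    a = (a_start + a_end) / 2.0
    total = 0.0
    for b, t in persons:
        total += (b / a) * math.log(t)
    return total / (len(persons) * math.log10(area_m2))


def random_net(
    rng: np.random.Generator,
    n_nodes: int = 5,
    max_states: int = 4,
    max_parents: int = 3,
) -> BeliefNetwork:
    """Random DAG over a random topological order with Dirichlet CPTs."""
    names = [f"v{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    cards = {n: int(rng.integers(2, max_states + 1)) for n in names}
    edges = []
    for pos, i in enumerate(order):
        preds = [names[j] for j in order[:pos]]
        k = int(rng.integers(0, min(len(preds), max_parents) + 1))
        for p in rng.choice(len(preds), size=k, replace=False) if k else []:
            edges.append((preds[int(p)], names[i]))
    structure = NetworkStructure(tuple(names), tuple(edges))
    states = {n: tuple(f"s{j}" for j in range(cards[n])) for n in names}
    tables = {}
    for n in names:
        parents = structure.parents(n)
        shape = tuple(cards[p] for p in parents)
        probs = rng.dirichlet(np.ones(cards[n]), size=shape).reshape(shape + (cards[n],))
        tables[n] = ConditionalTable(
            n, states[n], parents, tuple(states[p] for p in parents), probs
        )
    return BeliefNetwork(structure, tables)
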