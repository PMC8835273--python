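"""Discrete Bayesian belief network engine.

A belief network is a directed acyclic graph over categorical variables plus
one conditional probability table (CPT) per node; the joint distribution
factorizes as the product of the per-node conditionals.  This module houses
the representation, exact inference by variable elimination (min-fill
ordering, deterministic tie-breaks), data log-likelihood with missing cells
marginalized, and EM parameter learning with Dirichlet pseudo-count
smoothing.  Nets in this analysis stay small (<= ~20 nodes, <= 7 states), so
everything is exact; there is no sampling-based inference.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .domain import Dataset

__all__ = [
    "NetworkStructure",
    "ConditionalTable",
    "BeliefNetwork",
    "Evidence",
    "ImpossibleEvidenceError",
    "CyclicStructureError",
    "joint_probability",
    "marginal",
    "posterior",
    "evidence_probability",
    "log_likelihood",
    "predict_state",
    "target_posteriors",
    "EMSettings",
    "EMResult",
    "em_fit",
]

#: Partial assignment of observed states, variable -> state label.
Evidence = Mapping[str, str]

#: Floor applied to predicted probabilities before logs in evaluation.
PROB_FLOOR = 1e-9


class ImpossibleEvidenceError(ValueError):
    """Evidence has zero probability under the network."""


class CyclicStructureError(ValueError):
    """Edge set contains a directed cycle."""


# ---------------------------------------------------------------------------
# structure


@dataclass(frozen=True)
class NetworkStructure:
    """Node list plus directed (parent, child) edges; always acyclic."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple((p, c) for p, c in self.edges))
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for p, c in self.edges:
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge ({p!r}, {c!r}) references unknown node")
            if p == c:
                raise CyclicStructureError(f"self-loop on {p!r}")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicStructureError(f"directed cycle: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(c for p, c in self.edges if p == node)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def with_edge(self, parent: str, child: str) -> "NetworkStructure":
        return NetworkStructure(self.nodes, self.edges + ((parent, child),))

    def without_edge(self, parent: str, child: str) -> "NetworkStructure":
        return NetworkStructure(
            self.nodes, tuple(e for e in self.edges if e != (parent, child))
        )

    def with_reversed_edge(self, parent: str, child: str) -> "NetworkStructure":
        return self.without_edge(parent, child).with_edge(child, parent)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)


@dataclass(frozen=True)
class ConditionalTable:
    """CPT of one child: ``probs[parent codes..., child code]``.

    ``probs`` has one leading axis per parent (in ``parents`` order, sized
    by that parent's state count) and a trailing axis over the child's
    states; every row sums to 1.
    """

    child: str
    child_states: tuple[str, ...]
    parents: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        expected = tuple(len(s) for s in self.parent_states) + (len(self.child_states),)
        if probs.shape != expected:
            raise ValueError(
                f"CPT for {self.child!r}: shape {probs.shape} != expected {expected}"
            )
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError(f"CPT for {self.child!r}: probabilities outside [0, 1]")
        sums = probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"CPT for {self.child!r}: rows do not sum to 1")
        object.__setattr__(self, "probs", probs)

    def row(self, parent_assignment: Mapping[str, str]) -> np.ndarray:
        idx = tuple(
            states.index(parent_assignment[p])
            for p, states in zip(self.parents, self.parent_states)
        )
        return self.probs[idx]


@dataclass(frozen=True)
class BeliefNetwork:
    """Structure plus one CPT per node."""

    structure: NetworkStructure
    tables: Mapping[str, ConditionalTable]

    def __post_init__(self) -> None:
        missing = set(self.structure.nodes) - set(self.tables)
        if missing:
            raise ValueError(f"nodes without a CPT: {sorted(missing)}")
        for node in self.structure.nodes:
            cpt = self.tables[node]
            if cpt.child != node:
                raise ValueError(f"table under key {node!r} is for child {cpt.child!r}")
            if tuple(sorted(cpt.parents)) != tuple(sorted(self.structure.parents(node))):
                raise ValueError(
                    f"CPT parents {cpt.parents} of {node!r} do not match structure "
                    f"parents {self.structure.parents(node)}"
                )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.structure.nodes

    def states(self, node: str) -> tuple[str, ...]:
        return self.tables[node].child_states

    def card(self, node: str) -> int:
        return len(self.states(node))

    def state_index(self, node: str, state: str) -> int:
        try:
            return self.states(node).index(state)
        except ValueError:
            raise ValueError(f"{state!r} is not a state of node {node!r}") from None

    # -- JSON interchange --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "nodes": list(self.nodes),
            "states": {n: list(self.states(n)) for n in self.nodes},
            "edges": [list(e) for e in self.structure.edges],
            "cpts": {
                n: {
                    "parents": list(self.tables[n].parents),
                    "probs": self.tables[n].probs.tolist(),
                }
                for n in self.nodes
            },
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BeliefNetwork":
        text = Path(source).read_text() if isinstance(source, Path) else source
        doc = json.loads(text)
        structure = NetworkStructure(
            tuple(doc["nodes"]), tuple((p, c) for p, c in doc["edges"])
        )
        states = {n: tuple(s) for n, s in doc["states"].items()}
        tables = {}
        for node, entry in doc["cpts"].items():
            parents = tuple(entry["parents"])
            tables[node] = ConditionalTable(
                child=node,
                child_states=states[node],
                parents=parents,
                parent_states=tuple(states[p] for p in parents),
                probs=np.asarray(entry["probs"], dtype=float),
            )
        return cls(structure, tables)


def _validate_evidence(net: BeliefNetwork, evidence: Evidence) -> dict[str, int]:
    codes = {}
    for var, state in evidence.items():
        if var not in net.tables:
            raise ValueError(f"evidence variable {var!r} not in network")
        codes[var] = net.state_index(var, state)
    return codes


# ---------------------------------------------------------------------------
# factors and variable elimination


@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :], self.values.sum(axis=axis)
        )


def _product(factors: Sequence[_Factor]) -> _Factor:
    all_vars: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in all_vars:
                all_vars.append(v)
    all_vars_t = tuple(all_vars)
    out = np.ones((1,) * len(all_vars_t))
    for f in factors:
        shape = tuple(
            f.values.shape[f.vars.index(v)] if v in f.vars else 1 for v in all_vars_t
        )
        perm = tuple(f.vars.index(v) for v in all_vars_t if v in f.vars)
        out = out * np.transpose(f.values, perm).reshape(shape)
    return _Factor(all_vars_t, out)


def _reduced_factors(net: BeliefNetwork, ev_codes: Mapping[str, int]) -> list[_Factor]:
    factors = []
    for node in net.nodes:
        cpt = net.tables[node]
        fvars = cpt.parents + (node,)
        values = cpt.probs
        keep_vars = []
        for axis, var in enumerate(fvars):
            if var in ev_codes:
                values = np.take(values, ev_codes[var], axis=len(keep_vars))
            else:
                keep_vars.append(var)
        factors.append(_Factor(tuple(keep_vars), values))
    return factors


def _min_fill_order(factors: Sequence[_Factor], eliminate: set[str]) -> list[str]:
    # deterministic: ties broken lexicographically
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(f.vars)
    for v, ns in neighbors.items():
        ns.discard(v)
    order = []
    remaining = set(eliminate)
    while remaining:
        best = None
        for v in sorted(remaining):
            ns = neighbors.get(v, set())
            fill = sum(
                1
                for a in ns
                for b in ns
                if a < b and b not in neighbors.get(a, set())
            )
            if best is None or fill < best[0]:
                best = (fill, v)
        v = best[1]
        ns = neighbors.get(v, set())
        for a in ns:
            neighbors[a].update(ns - {a})
            neighbors[a].discard(v)
        neighbors.pop(v, None)
        remaining.discard(v)
        order.append(v)
    return order


def _eliminate(factors: list[_Factor], order: Iterable[str]) -> list[_Factor]:
    for var in order:
        bucket = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        if bucket:
            rest.append(_product(bucket).sum_out(var))
        factors = rest
    return factors


def marginal(
    net: BeliefNetwork, variables: Sequence[str], evidence: Evidence | None = None
) -> tuple[tuple[str, ...], np.ndarray]:
    """Joint posterior over ``variables`` given ``evidence``, by elimination.

    Returns ``(vars, array)`` with one axis per queried variable in the
    returned order; the array sums to 1.
    """
    evidence = dict(evidence or {})
    qset = list(dict.fromkeys(variables))
    for q in qset:
        if q in evidence:
            raise ValueError(f"query variable {q!r} is already in evidence")
        if q not in net.tables:
            raise ValueError(f"query variable {q!r} not in network")
    ev_codes = _validate_evidence(net, evidence)
    factors = _reduced_factors(net, ev_codes)
    eliminate = set(net.nodes) - set(qset) - set(evidence)
    order = _min_fill_order(factors, eliminate)
    remaining = _eliminate(factors, order)
    joint = _product(remaining)
    # align axes with the requested order
    perm = tuple(joint.vars.index(v) for v in qset)
    values = np.transpose(joint.values, perm) if perm else joint.values
    total = float(values.sum())
    if total <= 0:
        raise ImpossibleEvidenceError(f"evidence {evidence!r} has zero probability")
    return tuple(qset), values / total


def posterior(net: BeliefNetwork, query: str, evidence: Evidence | None = None) -> np.ndarray:
    """Normalized distribution of ``query`` given ``evidence``."""
    _, values = marginal(net, [query], evidence)
    return values


def evidence_probability(net: BeliefNetwork, evidence: Evidence) -> float:
    """Marginal probability of a (possibly partial) assignment."""
    ev_codes = _validate_evidence(net, evidence)
    factors = _reduced_factors(net, ev_codes)
    remaining = _eliminate(factors, _min_fill_order(factors, set(net.nodes) - set(evidence)))
    prob = 1.0
    for f in remaining:
        prob *= float(np.asarray(f.values).sum()) if f.vars else float(f.values)
    return prob


def joint_probability(net: BeliefNetwork, assignment: Mapping[str, str]) -> float:
    """Probability of a full assignment: product of per-node conditionals."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses nodes: {sorted(missing)}")
    prob = 1.0
    for node in net.nodes:
        cpt = net.tables[node]
        row = cpt.row({p: assignment[p] for p in cpt.parents})
        prob *= float(row[net.state_index(node, assignment[node])])
    return prob


def predict_state(
    net: BeliefNetwork, target: str, evidence: Evidence | None = None
) -> tuple[str, float]:
    """Most probable state of ``target``; ties go to the lowest state index."""
    p = posterior(net, target, evidence)
    idx = int(np.argmax(p))
    return net.states(target)[idx], float(p[idx])


# ---------------------------------------------------------------------------
# likelihood


def _record_evidence(ds: Dataset, codes: np.ndarray, cols: list[str], i: int) -> dict[str, str]:
    by_name = ds.spec_by_name()
    return {
        c: by_name[c].states[codes[i, j]] for j, c in enumerate(cols) if codes[i, j] >= 0
    }


def log_likelihood(net: BeliefNetwork, ds: Dataset) -> float:
    """Weighted log-likelihood of the dataset; missing cells marginalized.

    A record with probability zero contributes ``-inf`` and triggers a
    diagnostic warning naming the record.
    """
    cols = [c for c in ds.variable_columns() if c in net.tables]
    codes = ds.codes(cols)
    weights = ds.frame["weight"].to_numpy(dtype=float)
    total = 0.0
    complete = (codes >= 0).all(axis=1) if len(cols) == len(net.nodes) else np.zeros(len(codes), bool)
    for i in range(len(codes)):
        if complete[i]:
            assignment = _record_evidence(ds, codes, cols, i)
            p = joint_probability(net, assignment)
        else:
            p = evidence_probability(net, _record_evidence(ds, codes, cols, i))
        if p <= 0.0:
            warnings.warn(
                f"record {i} has probability 0 under the network; "
                "log-likelihood is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            return -math.inf
        total += weights[i] * math.log(p)
    return total


# ---------------------------------------------------------------------------
# EM parameter learning


@dataclass(frozen=True)
class EMSettings:
    """EM knobs: Dirichlet pseudo-count, relative-loglik tolerance, cap, seed."""

    pseudo_count: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0


@dataclass
class EMResult:
    net: BeliefNetwork
    loglik_trace: list[float]
    converged: bool
    n_iter: int


def _random_tables(
    structure: NetworkStructure,
    states: Mapping[str, tuple[str, ...]],
    rng: np.random.Generator,
) -> dict[str, ConditionalTable]:
    tables = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        shape = tuple(len(states[p]) for p in parents) + (len(states[node]),)
        probs = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1]).reshape(shape)
        tables[node] = ConditionalTable(
            node, states[node], parents, tuple(states[p] for p in parents), probs
        )
    return tables


def _normalize_counts(counts: np.ndarray, pseudo_count: float) -> np.ndarray:
    counts = counts + pseudo_count
    sums = counts.sum(axis=-1, keepdims=True)
    k = counts.shape[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / sums
    # parent combinations never seen: fall back to uniform
    probs = np.where(sums > 0, probs, 1.0 / k)
    return probs


def em_fit(
    structure: NetworkStructure,
    ds: Dataset,
    settings: EMSettings = EMSettings(),
) -> EMResult:
    """Fit CPTs to (possibly incomplete) records by expectation-maximization.

    Expected family counts are exact: rows whose whole family is observed
    are tallied directly (vectorized); for rows with missing family members
    the posterior over those members given the record's evidence is computed
    by variable elimination.  On complete data the first M-step already
    yields the pseudo-count-smoothed relative frequencies and EM stops after
    verifying convergence.  The log-likelihood trace is non-decreasing when
    ``pseudo_count = 0``; with smoothing the monotone objective is the
    Dirichlet-penalized likelihood.
    """
    if ds.n_records == 0:
        raise ValueError("cannot fit on an empty dataset")
    by_name = ds.spec_by_name()
    for node in structure.nodes:
        if node not in by_name:
            raise ValueError(f"structure node {node!r} has no variable spec in dataset")
    states = {n: by_name[n].states for n in structure.nodes}
    cols = list(structure.nodes)
    codes = ds.codes(cols)
    weights = ds.frame["weight"].to_numpy(dtype=float)
    col_idx = {c: j for j, c in enumerate(cols)}
    rng = np.random.default_rng(settings.seed)

    net = BeliefNetwork(structure, _random_tables(structure, states, rng))

    families = {
        node: (structure.parents(node) + (node,)) for node in structure.nodes
    }
    fam_cards = {
        node: tuple(len(states[v]) for v in fam) for node, fam in families.items()
    }

    complete_row = (codes >= 0).all(axis=1)
    incomplete_idx = np.flatnonzero(~complete_row)
    fam_observed = {
        node: (codes[:, [col_idx[v] for v in fam]] >= 0).all(axis=1)
        for node, fam in families.items()
    }

    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(settings.max_iter):
        n_iter = it + 1
        # E-step: expected family counts.  Fully observed families are
        # tallied vectorized; only families with missing members need
        # per-record inference.
        counts = {node: np.zeros(fam_cards[node]) for node in structure.nodes}
        loglik = 0.0
        for node, fam in families.items():
            obs = fam_observed[node]
            idx = tuple(codes[obs, col_idx[v]] for v in fam)
            np.add.at(counts[node], idx, weights[obs])
            # complete records' loglik contribution from this family
            comp_idx = tuple(codes[complete_row, col_idx[v]] for v in fam)
            probs = net.tables[node].probs[comp_idx]
            loglik += float(
                (weights[complete_row] * np.log(np.maximum(probs, 1e-300))).sum()
            )
        for i in incomplete_idx:
            row = codes[i]
            w = weights[i]
            observed = {c: states[c][row[j]] for c, j in col_idx.items() if row[j] >= 0}
            loglik += w * math.log(max(evidence_probability(net, observed), 1e-300))
            for node, fam in families.items():
                fam_missing = [v for v in fam if row[col_idx[v]] < 0]
                if not fam_missing:
                    continue  # already tallied vectorized
                qvars, post = marginal(net, fam_missing, observed)
                # scatter the posterior into the family count array
                idx_full: list[object] = []
                for v in fam:
                    if row[col_idx[v]] >= 0:
                        idx_full.append(row[col_idx[v]])
                    else:
                        idx_full.append(slice(None))
                post_axes = tuple(qvars.index(v) for v in fam if row[col_idx[v]] < 0)
                counts[node][tuple(idx_full)] += w * np.transpose(post, post_axes)
        trace.append(loglik)
        # M-step
        tables = {}
        for node, fam in families.items():
            parents = fam[:-1]
            tables[node] = ConditionalTable(
                node,
                states[node],
                parents,
                tuple(states[p] for p in parents),
                _normalize_counts(counts[node], settings.pseudo_count),
            )
        net = BeliefNetwork(structure, tables)
        if it > 0:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= settings.tol * max(1.0, abs(prev)):
                converged = True
                break
    if not converged:
        warnings.warn(
            f"EM did not converge within {settings.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return EMResult(net=net, loglik_trace=trace, converged=converged, n_iter=n_iter)


# ---------------------------------------------------------------------------
# fast per-target posteriors for held-out evaluation


def target_posteriors(net: BeliefNetwork, ds: Dataset, target: str) -> np.ndarray:
    """Posterior of ``target`` per record given all its other observed cells.

    Fast path: when every non-target network variable is observed in a
    record, only the target's own CPT and its children's CPTs matter
    (the rest of the network is fixed by evidence); that case is computed
    with vectorized table lookups.  Records with additional missing cells
    fall back to generic variable elimination.  Returns an (n_records,
    n_target_states) array of normalized posteriors.
    """
    cols = [c for c in ds.variable_columns() if c in net.tables]
    codes = ds.codes(cols)
    col_idx = {c: j for j, c in enumerate(cols)}
    if target not in col_idx:
        raise ValueError(f"target {target!r} not in dataset")
    n = len(codes)
    k = net.card(target)
    out = np.empty((n, k))

    non_target = [c for c in net.nodes if c != target]
    observed_mask = np.ones(n, dtype=bool)
    for c in non_target:
        observed_mask &= codes[:, col_idx[c]] >= 0

    fast = np.flatnonzero(observed_mask)
    if fast.size:
        log_p = np.zeros((fast.size, k))
        # target's own CPT row per record
        cpt = net.tables[target]
        if cpt.parents:
            idx = tuple(codes[fast, col_idx[p]] for p in cpt.parents)
            rows = cpt.probs[idx]
        else:
            rows = np.broadcast_to(cpt.probs, (fast.size, k))
        with np.errstate(divide="ignore"):
            log_p += np.log(np.maximum(rows, 1e-300))
            # children CPTs with the target axis left free
            for child in net.structure.children(target):
                ccpt = net.tables[child]
                # move the target's parent axis next to the child axis
                probs = np.moveaxis(ccpt.probs, ccpt.parents.index(target), -2)
                other_parents = [p for p in ccpt.parents if p != target]
                if other_parents:
                    idx3 = tuple(codes[fast, col_idx[p]] for p in other_parents)
                    sel = probs[idx3]  # (n_fast, k_target, k_child)
                else:
                    sel = np.broadcast_to(probs, (fast.size,) + probs.shape)
                child_codes = codes[fast, col_idx[child]]
                vals = sel[np.arange(fast.size), :, child_codes]
                log_p += np.log(np.maximum(vals, 1e-300))
        log_p -= log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p)
        out[fast] = p / p.sum(axis=1, keepdims=True)

    slow = np.flatnonzero(~observed_mask)
    by_name = ds.spec_by_name()
    for i in slow:
        evidence = {
            c: by_name[c].states[codes[i, col_idx[c]]]
            for c in non_target
            if codes[i, col_idx[c]] >= 0
        }
        out[i] = posterior(net, target, evidence)
    return out
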