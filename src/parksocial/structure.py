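"""Prior-constrained structure search with held-out selection.

The learning procedure mirrors a three-step workflow: (1) draft a network
from a-priori edges and tier constraints, (2) generate candidate structures
by random single-edge add/remove/reverse walks from the draft and fit each
by EM on the training split, (3) score every candidate on the held-out split
by per-target logarithmic loss and accuracy, and keep the most accurate
network.  An optional iterated mode re-drafts from the current best and
repeats, giving a stochastic local search while staying within the
candidate-generation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bbn import (
    PROB_FLOOR,
    BeliefNetwork,
    EMResult,
    EMSettings,
    NetworkStructure,
    em_fit,
    log_likelihood,
    target_posteriors,
)
from .domain import Dataset

__all__ = [
    "EdgeConstraints",
    "SplitSpec",
    "SearchSettings",
    "TargetMetrics",
    "CandidateResult",
    "split_dataset",
    "draft_network",
    "propose_candidates",
    "evaluate_candidate",
    "select_best",
    "search_structures",
]


@dataclass(frozen=True)
class EdgeConstraints:
    """Required/forbidden edges plus an optional tier ordering.

    ``tier_order`` lists tiers of variable names from upstream to
    downstream (e.g. spatial/individual -> activity -> interaction); edges
    pointing against the tier direction are forbidden.  Edges within a tier
    and skipping tiers forward are allowed.
    """

    required_edges: tuple[tuple[str, str], ...] = ()
    forbidden_edges: tuple[tuple[str, str], ...] = ()
    tier_order: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        req = set(self.required_edges)
        if req & set(self.forbidden_edges):
            raise ValueError("an edge cannot be both required and forbidden")
        for p, c in self.required_edges:
            if not self.allows(p, c):
                raise ValueError(f"required edge ({p!r}, {c!r}) violates constraints")

    def _tier(self, var: str) -> int | None:
        if self.tier_order is None:
            return None
        for i, tier in enumerate(self.tier_order):
            if var in tier:
                return i
        return None

    def allows(self, parent: str, child: str) -> bool:
        if (parent, child) in self.forbidden_edges:
            return False
        tp, tc = self._tier(parent), self._tier(child)
        if tp is not None and tc is not None and tp > tc:
            return False
        return True


@dataclass(frozen=True)
class SplitSpec:
    """Held-out split: disjoint, exhaustive train/test index sets."""

    test_fraction: float = 0.3
    seed: int = 0
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SearchSettings:
    """Candidate-generation knobs."""

    n_candidates: int = 200
    max_parents: int = 4
    mean_moves: float = 4.0  # geometric walk length
    rounds: int = 1  # iterated local search rounds
    seed: int = 0
    #: "accuracy" (ties by log loss) or "log_loss" (ties by accuracy).
    #: Argmax accuracy is blind to parents that move probability mass
    #: without flipping the modal state; log loss is strictly proper.
    selection_rule: str = "accuracy"


@dataclass(frozen=True)
class TargetMetrics:
    log_loss: float
    accuracy: float


@dataclass
class CandidateResult:
    structure: NetworkStructure
    fitted: BeliefNetwork
    train_loglik: float
    metrics: dict[str, TargetMetrics]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.metrics.values()]))

    @property
    def mean_log_loss(self) -> float:
        return float(np.mean([m.log_loss for m in self.metrics.values()]))


def split_dataset(ds: Dataset, split: SplitSpec) -> tuple[Dataset, Dataset]:
    """Seeded disjoint train/test split, optionally stratified."""
    rng = np.random.default_rng(split.seed)
    n = ds.n_records
    if n < 2:
        raise ValueError("need at least 2 records to split")
    test_idx: list[int] = []
    if split.stratify_by is not None:
        for _, grp in ds.frame.groupby(split.stratify_by, dropna=False, sort=True):
            idx = rng.permutation(grp.index.to_numpy())
            k = int(round(split.test_fraction * len(idx)))
            test_idx.extend(idx[:k].tolist())
    else:
        idx = rng.permutation(n)
        k = int(round(split.test_fraction * n))
        test_idx = idx[:k].tolist()
    test_set = set(test_idx)
    if not test_set or len(test_set) == n:
        raise ValueError("split left train or test empty; adjust test_fraction")
    train_idx = [i for i in range(n) if i not in test_set]
    return ds.subset(train_idx), ds.subset(sorted(test_set))


def draft_network(constraints: EdgeConstraints, variables: Sequence[str]) -> NetworkStructure:
    """Initial DAG from a-priori knowledge: exactly the required edges."""
    return NetworkStructure(tuple(variables), tuple(constraints.required_edges))


def _legal_moves(
    s: NetworkStructure, constraints: EdgeConstraints, max_parents: int
) -> list[tuple[str, str, str]]:
    edges = set(s.edges)
    moves: list[tuple[str, str, str]] = []
    n_parents = {v: len(s.parents(v)) for v in s.nodes}
    g = s.to_networkx()
    import networkx as nx

    for p in s.nodes:
        for c in s.nodes:
            if p == c or (p, c) in edges:
                continue
            if not constraints.allows(p, c) or n_parents[c] >= max_parents:
                continue
            if nx.has_path(g, c, p):  # adding p->c would close a cycle
                continue
            moves.append(("add", p, c))
    for p, c in edges:
        if (p, c) in constraints.required_edges:
            continue
        moves.append(("remove", p, c))
        if constraints.allows(c, p) and n_parents[p] < max_parents:
            g.remove_edge(p, c)
            if not nx.has_path(g, p, c):
                moves.append(("reverse", p, c))
            g.add_edge(p, c)
    return moves


def propose_candidates(
    draft: NetworkStructure,
    constraints: EdgeConstraints,
    n_candidates: int,
    max_parents: int = 4,
    seed: int = 0,
    mean_moves: float = 4.0,
) -> list[NetworkStructure]:
    """Random constraint-respecting mutations of the draft, deduplicated.

    The draft itself is always the first candidate; each further candidate
    applies a geometric-length walk of uniformly chosen legal add/remove/
    reverse moves.  Deterministic under the seed.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    seen = {draft.edge_set()}
    out = [draft]
    budget = 60 * n_candidates
    attempts = 0
    p_geom = min(1.0, 1.0 / max(mean_moves, 1e-9))
    while len(out) < n_candidates and attempts < budget:
        attempts += 1
        length = int(rng.geometric(p_geom))
        current = draft
        for _ in range(length):
            moves = _legal_moves(current, constraints, max_parents)
            if not moves:
                break
            kind, p, c = moves[int(rng.integers(len(moves)))]
            if kind == "add":
                current = current.with_edge(p, c)
            elif kind == "remove":
                current = current.without_edge(p, c)
            else:
                current = current.with_reversed_edge(p, c)
        key = current.edge_set()
        if key not in seen:
            seen.add(key)
            out.append(current)
    if not out:
        raise ValueError("constraint set admits no candidate structure")
    return out


def evaluate_candidate(
    structure: NetworkStructure,
    train: Dataset,
    test: Dataset,
    targets: Sequence[str],
    em_settings: EMSettings = EMSettings(),
) -> CandidateResult:
    """Fit by EM on the training split, score targets on the held-out split.

    For every test record and target, the posterior of the target given all
    other observed variables is computed; log loss is the mean negative log
    probability assigned to the observed state (floored at 1e-9), accuracy
    the fraction of records whose most probable state matches.
    """
    for t in targets:
        if t not in structure.nodes:
            raise ValueError(f"target {t!r} not in structure")
    fit = em_fit(structure, train, em_settings)
    metrics: dict[str, TargetMetrics] = {}
    for t in targets:
        observed = test.frame[t]
        mask = observed.notna().to_numpy()
        if not mask.any():
            raise ValueError(f"target {t!r} is fully missing in the test split")
        post = target_posteriors(fit.net, test, t)[mask]
        spec = test.spec_by_name()[t]
        obs_codes = np.array([spec.state_index(s) for s in observed[mask]])
        p_obs = post[np.arange(len(obs_codes)), obs_codes]
        log_loss = float(np.mean(-np.log(np.maximum(p_obs, PROB_FLOOR))))
        accuracy = float(np.mean(np.argmax(post, axis=1) == obs_codes))
        metrics[t] = TargetMetrics(log_loss=log_loss, accuracy=accuracy)
    return CandidateResult(
        structure=structure,
        fitted=fit.net,
        train_loglik=fit.loglik_trace[-1],
        metrics=metrics,
    )


def select_best(
    candidates: Sequence[CandidateResult], selection_rule: str = "accuracy"
) -> CandidateResult:
    """Highest mean target accuracy; ties: lower mean log loss, fewer edges.

    ``selection_rule="log_loss"`` instead minimizes mean log loss with
    accuracy as the tie-break.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    if selection_rule == "accuracy":
        key = lambda c: (c.mean_accuracy, -c.mean_log_loss, -len(c.structure.edges))
    elif selection_rule == "log_loss":
        key = lambda c: (-c.mean_log_loss, c.mean_accuracy, -len(c.structure.edges))
    else:
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    best = candidates[0]
    for c in candidates[1:]:
        if key(c) > key(best):
            best = c
    return best


def search_structures(
    train: Dataset,
    test: Dataset,
    constraints: EdgeConstraints,
    variables: Sequence[str],
    targets: Sequence[str],
    search: SearchSettings = SearchSettings(),
    em_settings: EMSettings = EMSettings(),
) -> tuple[CandidateResult, list[CandidateResult]]:
    """Full draft -> candidates -> evaluate -> select loop.

    With ``search.rounds > 1`` the selected structure seeds the next round's
    walks (iterated local search).  Returns the winner and the evaluated
    candidate ledger across all rounds.
    """
    draft = draft_network(constraints, variables)
    rng = np.random.default_rng(search.seed)
    ledger: list[CandidateResult] = []
    seen: set[frozenset] = set()
    best: CandidateResult | None = None
    current = draft
    for _ in range(max(1, search.rounds)):
        cands = propose_candidates(
            current,
            constraints,
            search.n_candidates,
            max_parents=search.max_parents,
            seed=int(rng.integers(2**31 - 1)),
            mean_moves=search.mean_moves,
        )
        for s in cands:
            if s.edge_set() in seen:
                continue
            seen.add(s.edge_set())
            ledger.append(evaluate_candidate(s, train, test, targets, em_settings))
        best = select_best(ledger, search.selection_rule)
        current = best.structure
    assert best is not None
    return best, ledger
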