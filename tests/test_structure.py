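import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_net
from test_bbn import dataset_from_codes, sample_dataset
from parksocial.bbn import EMSettings, NetworkStructure
from parksocial.structure import (
    CandidateResult,
    EdgeConstraints,
    SearchSettings,
    SplitSpec,
    TargetMetrics,
    draft_network,
    evaluate_candidate,
    propose_candidates,
    search_structures,
    select_best,
    split_dataset,
)

TIERS = (("s1", "s2", "g"), ("act",), ("out",))
VARS = ("s1", "s2", "g", "act", "out")


class TestConstraints:
    def test_required_and_forbidden_disjoint(self):
        with pytest.raises(ValueError):
            EdgeConstraints(required_edges=(("a", "b"),), forbidden_edges=(("a", "b"),))

    def test_tier_direction(self):
        c = EdgeConstraints(tier_order=TIERS)
        assert c.allows("s1", "act") and c.allows("act", "out")
        assert c.allows("s1", "out")  # skipping forward is fine
        assert c.allows("s1", "s2")  # within-tier allowed
        assert not c.allows("out", "act")
        assert not c.allows("act", "s1")

    def test_required_edge_against_tier_rejected(self):
        with pytest.raises(ValueError):
            EdgeConstraints(required_edges=(("out", "s1"),), tier_order=TIERS)


class TestDraft:
    def test_draft_contains_exactly_required_edges(self):
        c = EdgeConstraints(required_edges=(("act", "out"),), tier_order=TIERS)
        draft = draft_network(c, VARS)
        assert draft.edges == (("act", "out"),)

    def test_empty_constraints_give_edgeless_dag(self):
        assert draft_network(EdgeConstraints(), VARS).edges == ()

    def test_cyclic_required_set_rejected(self):
        c = EdgeConstraints(required_edges=(("a", "b"), ("b", "a")))
        with pytest.raises(Exception):
            draft_network(c, ("a", "b"))


class TestProposeCandidates:
    def test_single_candidate_is_the_draft(self):
        c = EdgeConstraints(tier_order=TIERS)
        draft = draft_network(c, VARS)
        assert propose_candidates(draft, c, 1, seed=0) == [draft]

    def test_forbidden_edge_never_appears(self):
        c = EdgeConstraints(forbidden_edges=(("s1", "out"),), tier_order=TIERS)
        draft = draft_network(c, VARS)
        for cand in propose_candidates(draft, c, 200, seed=1):
            assert ("s1", "out") not in cand.edge_set()
            for p, q in cand.edges:
                assert c.allows(p, q)

    def test_required_edges_always_present(self):
        c = EdgeConstraints(required_edges=(("act", "out"),), tier_order=TIERS)
        draft = draft_network(c, VARS)
        for cand in propose_candidates(draft, c, 100, seed=2):
            assert ("act", "out") in cand.edge_set()

    def test_deterministic_under_seed(self):
        c = EdgeConstraints(tier_order=TIERS)
        draft = draft_network(c, VARS)
        a = propose_candidates(draft, c, 50, seed=3)
        b = propose_candidates(draft, c, 50, seed=3)
        assert [x.edge_set() for x in a] == [x.edge_set() for x in b]

    def test_candidates_deduplicated_and_within_parent_budget(self):
        c = EdgeConstraints(tier_order=TIERS)
        draft = draft_network(c, VARS)
        cands = propose_candidates(draft, c, 80, max_parents=2, seed=4)
        keys = [x.edge_set() for x in cands]
        assert len(set(keys)) == len(keys)
        for cand in cands:
            assert max(len(cand.parents(v)) for v in cand.nodes) <= 2


class TestSplit:
    def test_disjoint_and_exhaustive(self, chain_net):
        rng = np.random.default_rng(0)
        ds = sample_dataset(chain_net, 100, rng)
        train, test = split_dataset(ds, SplitSpec(0.3, seed=1))
        assert train.n_records == 70 and test.n_records == 30

    def test_stratified_split_preserves_group_shares(self, chain_net):
        rng = np.random.default_rng(1)
        ds = sample_dataset(chain_net, 200, rng)
        train, test = split_dataset(ds, SplitSpec(0.25, seed=2, stratify_by="A"))
        for a in ("a", "a2"):
            total = (ds.frame["A"] == a).sum()
            in_test = (test.frame["A"] == a).sum()
            assert in_test == round(0.25 * total)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(1.5)


class TestEvaluate:
    def test_perfect_oracle_scores_zero_loss(self, copy_net):
        rng = np.random.default_rng(2)
        ds = sample_dataset(copy_net, 200, rng)
        train, test = split_dataset(ds, SplitSpec(0.3, seed=0))
        res = evaluate_candidate(
            copy_net.structure, train, test, ["Y"], EMSettings(pseudo_count=0.0, seed=0)
        )
        assert res.metrics["Y"].accuracy == 1.0
        assert res.metrics["Y"].log_loss == pytest.approx(0.0, abs=1e-12)

    def test_uniform_predictor_log_loss_is_log_k(self):
        states = {"T": tuple(f"s{i}" for i in range(5)), "E": ("e0", "e1")}
        net = make_net([], states, {"T": [0.2] * 5, "E": [0.5, 0.5]})
        rng = np.random.default_rng(3)
        ds = sample_dataset(net, 60, rng)
        from parksocial.bbn import target_posteriors

        post = target_posteriors(net, ds, "T")
        np.testing.assert_allclose(post, 0.2, atol=1e-12)
        spec = ds.spec_by_name()["T"]
        codes = [spec.state_index(s) for s in ds.frame["T"]]
        log_loss = float(np.mean(-np.log(post[np.arange(len(codes)), codes])))
        assert log_loss == pytest.approx(math.log(5), abs=1e-9)

    def test_fully_missing_target_rejected(self, chain_net):
        rng = np.random.default_rng(4)
        ds = sample_dataset(chain_net, 50, rng)
        train, test = split_dataset(ds, SplitSpec(0.3, seed=0))
        test.frame["B"] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            evaluate_candidate(chain_net.structure, train, test, ["B"], EMSettings(seed=0))

    def test_true_structure_beats_edgeless_on_log_loss(self, copy_net):
        rng = np.random.default_rng(5)
        ds = sample_dataset(copy_net, 300, rng)
        train, test = split_dataset(ds, SplitSpec(0.3, seed=1))
        em = EMSettings(pseudo_count=1.0, seed=0)
        with_edge = evaluate_candidate(copy_net.structure, train, test, ["Y"], em)
        edgeless = evaluate_candidate(
            NetworkStructure(copy_net.nodes, ()), train, test, ["Y"], em
        )
        assert with_edge.metrics["Y"].log_loss < edgeless.metrics["Y"].log_loss

    def test_no_leakage_metrics_reproducible(self, chain_net):
        rng = np.random.default_rng(6)
        ds = sample_dataset(chain_net, 120, rng)
        train, test = split_dataset(ds, SplitSpec(0.3, seed=2))
        em = EMSettings(seed=0)
        first = evaluate_candidate(chain_net.structure, train, test, ["B"], em)
        again = evaluate_candidate(chain_net.structure, train, test, ["B"], em)
        assert first.metrics == again.metrics


class TestSelectBest:
    def _cand(self, acc, loss, n_edges=0):
        edges = tuple((f"n{i}", "t") for i in range(n_edges))
        s = NetworkStructure(("t",) + tuple(f"n{i}" for i in range(max(n_edges, 1))), edges)
        return CandidateResult(
            structure=s, fitted=None, train_loglik=0.0,
            metrics={"t": TargetMetrics(log_loss=loss, accuracy=acc)},
        )

    def test_single_candidate(self):
        c = self._cand(0.5, 1.0)
        assert select_best([c]) is c

    def test_accuracy_primary_log_loss_tiebreak(self):
        worse = self._cand(0.7, 1.2)
        better = self._cand(0.7, 0.9)
        assert select_best([worse, better]) is better
        higher_acc = self._cand(0.8, 2.0)
        assert select_best([worse, better, higher_acc]) is higher_acc

    def test_edge_count_final_tiebreak(self):
        big = self._cand(0.7, 1.0, n_edges=3)
        small = self._cand(0.7, 1.0, n_edges=1)
        assert select_best([big, small]) is small

    def test_log_loss_rule(self):
        a = self._cand(0.9, 1.5)
        b = self._cand(0.2, 0.5)
        assert select_best([a, b], "log_loss") is b

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestSearch:
    def test_more_data_does_not_hurt(self, copy_net):
        """Mean selected test log loss at n=2000 <= at n=200 (10 replicates)."""
        em = EMSettings(pseudo_count=1.0, seed=0)
        c = EdgeConstraints(tier_order=(("X",), ("Y",)))
        losses = {200: [], 2000: []}
        for rep in range(10):
            for n in (200, 2000):
                rng = np.random.default_rng(1000 + rep)
                ds = sample_dataset(copy_net, n, rng)
                train, test = split_dataset(ds, SplitSpec(0.3, seed=rep))
                best, _ = search_structures(
                    train, test, c, copy_net.nodes, ["Y"],
                    SearchSettings(n_candidates=8, seed=rep, selection_rule="log_loss"),
                    em,
                )
                losses[n].append(best.metrics["Y"].log_loss)
        assert np.mean(losses[2000]) <= np.mean(losses[200]) + 1e-9
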