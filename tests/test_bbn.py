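import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_net
from oracles import enum_evidence_probability, enum_posterior, random_net
from parksocial.bbn import (
    BeliefNetwork,
    CyclicStructureError,
    EMSettings,
    ImpossibleEvidenceError,
    NetworkStructure,
    em_fit,
    evidence_probability,
    joint_probability,
    log_likelihood,
    posterior,
    predict_state,
    target_posteriors,
)
from parksocial.domain import Dataset, VariableSpec


def dataset_from_codes(net, codes_frame):
    specs = [
        VariableSpec(n, "spatial", net.states(n)) for n in net.nodes
    ]
    return Dataset(specs, codes_frame.copy(), provenance="synthetic")


def sample_dataset(net, n, rng, missing_rate=0.0):
    order = net.structure.topological_order()
    cols = {}
    for node in order:
        cpt = net.tables[node]
        if cpt.parents:
            idx = tuple(cols[p] for p in cpt.parents)
            rows = cpt.probs[idx]
        else:
            rows = np.broadcast_to(cpt.probs, (n, net.card(node)))
        u = rng.random(n)
        cols[node] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
    frame = pd.DataFrame(
        {node: [net.states(node)[c] for c in cols[node]] for node in net.nodes},
        dtype=object,
    )
    if missing_rate:
        mask = rng.random(frame.shape) < missing_rate
        frame = frame.mask(pd.DataFrame(mask, columns=frame.columns))
    return dataset_from_codes(net, frame)


class TestStructure:
    def test_cycle_rejected(self):
        with pytest.raises(CyclicStructureError):
            NetworkStructure(("a", "b"), (("a", "b"), ("b", "a")))

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            NetworkStructure(("a",), (("a", "z"),))

    def test_edge_mutations(self):
        s = NetworkStructure(("a", "b", "c"), (("a", "b"),))
        assert s.with_edge("b", "c").edges == (("a", "b"), ("b", "c"))
        assert s.without_edge("a", "b").edges == ()
        assert s.with_reversed_edge("a", "b").edges == (("b", "a"),)


class TestJointAndPosterior:
    def test_single_uniform_node(self):
        net = make_net([], {"A": ("a", "b")}, {"A": [0.5, 0.5]})
        assert joint_probability(net, {"A": "a"}) == 0.5

    def test_chain_product_rule(self, chain_net):
        assert joint_probability(chain_net, {"A": "a", "B": "b"}) == pytest.approx(0.27)

    def test_joint_sums_to_one_on_random_net(self):
        rng = np.random.default_rng(0)
        net = random_net(rng, n_nodes=5)
        total = sum(
            joint_probability(net, dict(zip(net.nodes, combo)))
            for combo in itertools.product(*(net.states(n) for n in net.nodes))
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_evidence_is_prior_marginal(self, chain_net):
        np.testing.assert_allclose(posterior(chain_net, "A"), [0.3, 0.7], atol=1e-12)
        np.testing.assert_allclose(
            posterior(chain_net, "B"), [0.3 * 0.9 + 0.7 * 0.2, 0.3 * 0.1 + 0.7 * 0.8]
        )

    def test_bayes_rule_by_hand(self, chain_net):
        # P(A=a | B=b) = .3*.9 / (.3*.9 + .7*.2) = 27/41
        np.testing.assert_allclose(
            posterior(chain_net, "A", {"B": "b"}), [27 / 41, 14 / 41], atol=1e-12
        )

    def test_evidence_on_only_parent_returns_cpt_row(self, chain_net):
        np.testing.assert_allclose(posterior(chain_net, "B", {"A": "a"}), [0.9, 0.1])

    def test_impossible_evidence_raises(self, copy_net):
        net = make_net(
            [("X", "Y")],
            {"X": ("h", "t"), "Y": ("h", "t")},
            {"X": [1.0, 0.0], "Y": [[1.0, 0.0], [0.0, 1.0]]},
        )
        with pytest.raises(ImpossibleEvidenceError):
            posterior(net, "X", {"Y": "t"})

    def test_posteriors_normalized_on_random_nets(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            net = random_net(rng, n_nodes=6)
            query = net.nodes[int(rng.integers(len(net.nodes)))]
            ev_nodes = [n for n in net.nodes if n != query][:2]
            evidence = {n: net.states(n)[0] for n in ev_nodes}
            try:
                p = posterior(net, query, evidence)
            except ImpossibleEvidenceError:
                continue
            assert abs(p.sum() - 1.0) < 1e-9
            np.testing.assert_allclose(p, enum_posterior(net, query, evidence), atol=1e-10)

    def test_evidence_probability_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            net = random_net(rng, n_nodes=5)
            ev_nodes = list(net.nodes[:2])
            evidence = {
                n: net.states(n)[int(rng.integers(net.card(n)))] for n in ev_nodes
            }
            assert evidence_probability(net, evidence) == pytest.approx(
                enum_evidence_probability(net, evidence), abs=1e-12
            )


class TestPredictState:
    def test_degenerate_cpt(self, copy_net):
        state, p = predict_state(copy_net, "Y", {"X": "t"})
        assert (state, p) == ("t", 1.0)

    def test_uniform_tie_breaks_to_first_state(self):
        net = make_net([], {"A": ("s0", "s1", "s2")}, {"A": [1 / 3] * 3})
        state, p = predict_state(net, "A")
        assert state == "s0" and p == pytest.approx(1 / 3)

    def test_argmax_agrees_with_enumeration(self):
        rng = np.random.default_rng(3)
        net = random_net(rng, n_nodes=5)
        query = net.nodes[0]
        evidence = {net.nodes[-1]: net.states(net.nodes[-1])[0]}
        if query in evidence:
            return
        state, _ = predict_state(net, query, evidence)
        oracle = enum_posterior(net, query, evidence)
        assert state == net.states(query)[int(np.argmax(oracle))]


class TestLogLikelihood:
    def test_certain_record_scores_zero(self):
        net = make_net([], {"A": ("a", "b")}, {"A": [1.0, 0.0]})
        ds = dataset_from_codes(net, pd.DataFrame({"A": ["a"]}, dtype=object))
        assert log_likelihood(net, ds) == 0.0

    def test_two_fair_coins(self):
        net = make_net(
            [], {"A": ("h", "t"), "B": ("h", "t")}, {"A": [0.5, 0.5], "B": [0.5, 0.5]}
        )
        ds = dataset_from_codes(net, pd.DataFrame({"A": ["h"], "B": ["t"]}, dtype=object))
        assert log_likelihood(net, ds) == pytest.approx(math.log(0.25))

    def test_missing_cell_marginalized(self, chain_net):
        ds = dataset_from_codes(
            chain_net, pd.DataFrame({"A": [np.nan], "B": ["b"]}, dtype=object)
        )
        # P(B=b) = .3*.9 + .7*.2 = .41
        assert log_likelihood(chain_net, ds) == pytest.approx(math.log(0.41))

    def test_zero_probability_record_reports_neg_inf(self):
        net = make_net([], {"A": ("a", "b")}, {"A": [1.0, 0.0]})
        ds = dataset_from_codes(net, pd.DataFrame({"A": ["b"]}, dtype=object))
        with pytest.warns(RuntimeWarning, match="probability 0"):
            assert log_likelihood(net, ds) == -math.inf


class TestEM:
    def test_complete_data_ml_frequencies(self, chain_net):
        rng = np.random.default_rng(4)
        ds = sample_dataset(chain_net, 400, rng)
        fit = em_fit(chain_net.structure, ds, EMSettings(pseudo_count=0.0, seed=0))
        # independent tally with pandas
        pa = (ds.frame["A"] == "a").mean()
        np.testing.assert_allclose(fit.net.tables["A"].probs, [pa, 1 - pa], atol=1e-12)
        for i, a in enumerate(("a", "a2")):
            sub = ds.frame[ds.frame["A"] == a]
            freq = (sub["B"] == "b").mean()
            np.testing.assert_allclose(
                fit.net.tables["B"].probs[i], [freq, 1 - freq], atol=1e-12
            )

    def test_complete_data_laplace_smoothing(self, chain_net):
        rng = np.random.default_rng(5)
        ds = sample_dataset(chain_net, 100, rng)
        fit = em_fit(chain_net.structure, ds, EMSettings(pseudo_count=1.0, seed=0))
        n_a = (ds.frame["A"] == "a").sum()
        expected = (n_a + 1) / (100 + 2)
        assert fit.net.tables["A"].probs[0] == pytest.approx(expected, abs=1e-12)

    def test_em_beats_random_parameterizations(self, chain_net):
        """EM on 20%-missing data reaches a likelihood no random guess beats."""
        rng = np.random.default_rng(6)
        ds = sample_dataset(chain_net, 150, rng, missing_rate=0.2)
        fit = em_fit(chain_net.structure, ds, EMSettings(pseudo_count=0.0, seed=1))
        em_ll = log_likelihood(fit.net, ds)
        states = {"A": ("a", "a2"), "B": ("b", "b2")}
        for _ in range(1000):
            pa, pb1, pb2 = rng.random(3)
            guess = make_net(
                [("A", "B")],
                states,
                {"A": [pa, 1 - pa], "B": [[pb1, 1 - pb1], [pb2, 1 - pb2]]},
            )
            assert log_likelihood(guess, ds) <= em_ll + 1e-6

    def test_empty_dataset_rejected(self, chain_net):
        ds = dataset_from_codes(chain_net, pd.DataFrame({"A": [], "B": []}, dtype=object))
        with pytest.raises(ValueError):
            em_fit(chain_net.structure, ds)

    def test_non_convergence_warns(self, chain_net):
        rng = np.random.default_rng(7)
        ds = sample_dataset(chain_net, 200, rng, missing_rate=0.3)
        with pytest.warns(RuntimeWarning, match="converge"):
            res = em_fit(chain_net.structure, ds, EMSettings(max_iter=2, seed=0))
        assert not res.converged


class TestTargetPosteriors:
    def test_matches_generic_posterior(self):
        rng = np.random.default_rng(8)
        net = random_net(rng, n_nodes=6, max_states=3)
        ds = sample_dataset(net, 40, rng, missing_rate=0.1)
        target = net.nodes[2]
        fast = target_posteriors(net, ds, target)
        by_name = ds.spec_by_name()
        for i, rec in enumerate(ds.records):
            evidence = {
                k: v for k, v in rec.values.items() if v is not None and k != target
            }
            np.testing.assert_allclose(
                fast[i], posterior(net, target, evidence), atol=1e-9
            )


class TestJsonInterchange:
    def test_round_trip(self):
        rng = np.random.default_rng(9)
        net = random_net(rng, n_nodes=5)
        back = BeliefNetwork.from_json(net.to_json())
        assert back.structure.edges == net.structure.edges
        for n in net.nodes:
            np.testing.assert_allclose(back.tables[n].probs, net.tables[n].probs)
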