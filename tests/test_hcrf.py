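"""Inference, gradient and training checks against exact enumeration."""

import numpy as np
import pytest

from adrnet.hcrf import (
    DivergenceError,
    ModelError,
    brute_force_infer,
    build_model,
    gradient,
    infer,
    log_likelihood,
    objective,
    potential,
    predict,
    train,
    HCRFModel,
)

from conftest import make_net, random_model


def assert_result_invariants(res, model):
    for ek, t in res.edge_marginals.items():
        assert abs(t.sum() - 1.0) < 1e-9
        _, u, v = ek
        np.testing.assert_allclose(t.sum(axis=1)[1], res.node_marginals[u], atol=1e-7)
        np.testing.assert_allclose(t.sum(axis=0)[1], res.node_marginals[v], atol=1e-7)
    for p in res.node_marginals.values():
        assert -1e-9 <= p <= 1 + 1e-9


class TestBuildModel:
    def test_zero_init_all_zero(self, small_net):
        m = build_model(small_net, init="zero")
        assert all(np.all(t == 0) for t in m.params.values())
        assert set(m.params) == set(small_net.edges)

    def test_same_seed_reproducible_and_seeds_differ(self, small_net):
        a = build_model(small_net, init="gaussian", seed=3)
        b = build_model(small_net, init="gaussian", seed=3)
        c = build_model(small_net, init="gaussian", seed=4)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_missing_end_layer_rejected(self):
        no_drugs = make_net([("p1", "E2"), ("a1", "E4")], [])
        with pytest.raises(ModelError):
            build_model(no_drugs)

    def test_roles_follow_layers(self, chain_net):
        m = build_model(chain_net)
        assert m.roles == {"d1": "input", "p1": "hidden", "w1": "hidden",
                           "a1": "outcome"}


class TestPotential:
    def test_zero_params_zero_potential(self, small_net):
        m = build_model(small_net, init="zero")
        a = {n: 1 for n in m.node_ids}
        assert potential(m, a) == 0.0

    def test_single_edge_reads_table_entry(self, chain_net):
        m = build_model(chain_net, init="zero")
        m.params[("R1", "d1", "p1")][1, 1] = 2.0
        a = {"d1": 1, "p1": 1, "w1": 0, "a1": 0}
        assert potential(m, a) == 2.0

    def test_additive_over_edges(self, small_net):
        m = build_model(small_net, init="gaussian", seed=1)
        a = {n: i % 2 for i, n in enumerate(m.node_ids)}
        total = sum(m.theta(ek)[a[ek[1]], a[ek[2]]] for ek in m.edge_keys)
        assert potential(m, a) == pytest.approx(total, abs=1e-12)


class TestInferOracle:
    def test_uniform_at_zero_params(self, small_net):
        m = build_model(small_net, init="zero")
        res = infer(m)
        assert all(p == pytest.approx(0.5, abs=1e-12) for p in res.node_marginals.values())
        assert res.log_partition == pytest.approx(len(m.node_ids) * np.log(2), abs=1e-9)

    def test_two_node_closed_form(self):
        # one hidden node linked to one clamped node in state 1:
        # P(hidden=1) = e^{t[1,1]} / (e^{t[1,0]} + e^{t[1,1]})
        net = make_net([("d1", "E1"), ("p1", "E2"), ("w1", "E3"), ("a1", "E4")],
                       [("R1", "d1", "p1"), ("R4", "p1", "w1"), ("R5", "w1", "a1")])
        m = build_model(net, init="gaussian", seed=2)
        t = m.params[("R1", "d1", "p1")]
        # isolate the d1-p1 edge by zeroing the rest
        m.params[("R4", "p1", "w1")][:] = 0
        m.params[("R5", "w1", "a1")][:] = 0
        res = infer(m, {"d1": 1})
        want = np.exp(t[1, 1]) / (np.exp(t[1, 0]) + np.exp(t[1, 1]))
        assert res.node_marginals["p1"] == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_models_match_enumeration(self, seed):
        """On acyclic instances BP must be exact to 1e-9."""
        net = make_net(
            [("d1", "E1"), ("d2", "E1"), ("p1", "E2"), ("p2", "E2"),
             ("w1", "E3"), ("a1", "E4"), ("a2", "E4")],
            [("R1", "d1", "p1"), ("R2", "d2", "p2"), ("R4", "p1", "w1"),
             ("R4", "p2", "w1"), ("R5", "w1", "a1"), ("R5", "w1", "a2")],
        )
        m = build_model(net, init="gaussian", init_scale=1.2, seed=seed)
        for clamps in ({}, {"d1": 1, "d2": 0}, {"d1": 1, "a1": 1, "a2": 0}):
            bp, bf = infer(m, clamps), brute_force_infer(m, clamps)
            assert bp.converged
            for n in m.node_ids:
                assert bp.node_marginals[n] == pytest.approx(
                    bf.node_marginals[n], abs=1e-9)
            assert bp.log_partition == pytest.approx(bf.log_partition, abs=1e-9)
            for ek in m.edge_keys:
                np.testing.assert_allclose(
                    bp.edge_marginals[ek], bf.edge_marginals[ek], atol=1e-9)
            assert_result_invariants(bp, m)

    @pytest.mark.parametrize("seed", range(8))
    def test_weakly_coupled_loopy_close_to_enumeration(self, seed):
        m = random_model(3, 3, 2, 3, scale=0.5, seed=seed)
        bp, bf = infer(m), brute_force_infer(m)
        for n in m.node_ids:
            assert abs(bp.node_marginals[n] - bf.node_marginals[n]) < 0.05

    def test_nonconvergence_flagged_not_raised(self):
        m = random_model(4, 4, 3, 3, scale=4.0, seed=0)
        res = infer(m, max_iter=3)
        assert res.converged is False

    def test_clamp_on_unknown_node_rejected(self, chain_net):
        m = build_model(chain_net)
        with pytest.raises(ModelError):
            infer(m, {"ghost": 1})


class TestBruteForce:
    def test_zero_params_log_partition(self, chain_net):
        m = build_model(chain_net, init="zero")
        res = brute_force_infer(m, {"d1": 0})
        assert res.log_partition == pytest.approx(3 * np.log(2), abs=1e-12)

    def test_single_edge_joint(self):
        net = make_net([("d1", "E1"), ("p1", "E2"), ("w1", "E3"), ("a1", "E4")],
                       [("R1", "d1", "p1"), ("R4", "p1", "w1"), ("R5", "w1", "a1")])
        m = build_model(net, init="zero")
        m.params[("R1", "d1", "p1")][1, 1] = 1.0
        res = brute_force_infer(m)
        # P(d1=p1=1) = e / (3 + e), marginalized over the uncoupled rest
        assert res.edge_marginals[("R1", "d1", "p1")][1, 1] == pytest.approx(
            np.e / (3 + np.e), abs=1e-12)

    def test_refuses_large_state_space(self):
        m = random_model(10, 8, 5, 6, seed=0)
        with pytest.raises(ModelError, match="free nodes"):
            brute_force_infer(m)


class TestLikelihoodAndGradient:
    def test_zero_params_conditional_is_uniform(self, small_net):
        m = build_model(small_net, init="zero")
        x = {d: 1 for d in m.inputs()}
        y = {o: 1 for o in m.outcomes()}
        assert log_likelihood(m, x, y) == pytest.approx(
            -len(m.outcomes()) * np.log(2), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_trees(self, seed, small_net):
        m = build_model(small_net, init="gaussian", seed=seed)
        x = {d: seed % 2 for d in m.inputs()}
        y = {o: 1 for o in m.outcomes()}
        got = log_likelihood(m, x, y)
        want = log_likelihood(m, x, y, infer_fn=brute_force_infer)
        assert got == pytest.approx(want, abs=1e-9)

    def test_disconnected_hidden_node_cancels(self, chain_net):
        m = build_model(chain_net, init="gaussian", seed=1)
        base = log_likelihood(m, {"d1": 1}, {"a1": 1})
        bigger = make_net(
            [("d1", "E1"), ("p1", "E2"), ("p9", "E2"), ("w1", "E3"), ("a1", "E4")],
            [("R1", "d1", "p1"), ("R4", "p1", "w1"), ("R5", "w1", "a1")],
        )
        m2 = build_model(bigger, init="zero")
        for k in m.params:
            m2.params[k] = m.params[k].copy()
        assert log_likelihood(m2, {"d1": 1}, {"a1": 1}) == pytest.approx(base, abs=1e-9)

    def test_objective_penalty_monotone_in_sigma2(self, small_net):
        m = build_model(small_net, init="gaussian", seed=0)
        x = {d: 1 for d in m.inputs()}
        y = {o: 0 for o in m.outcomes()}
        assert objective(m, [(x, y)], sigma2=0.5) < objective(m, [(x, y)], sigma2=5.0)

    def test_gradient_at_zero_hidden_outcome_edge(self):
        # spec of the clamped expectation at theta = 0: mass only on
        # configurations whose outcome side matches the clamp
        net = make_net([("d1", "E1"), ("p1", "E2"), ("w1", "E3"), ("a1", "E4")],
                       [("R1", "d1", "p1"), ("R4", "p1", "w1"), ("R5", "w1", "a1")])
        m = build_model(net, init="zero")
        g = gradient(m, {"d1": 1}, {"a1": 1}, sigma2=np.inf)
        np.testing.assert_allclose(
            g[("R5", "w1", "a1")], [[-0.25, 0.25], [-0.25, 0.25]], atol=1e-9)

    def test_large_sigma2_removes_regularizer(self, small_net):
        m = build_model(small_net, init="gaussian", seed=3)
        x = {d: 0 for d in m.inputs()}
        y = {o: 1 for o in m.outcomes()}
        g_inf = gradient(m, x, y, sigma2=1e12)
        g_small = gradient(m, x, y, sigma2=1.0)
        k = m.edge_keys[0]
        np.testing.assert_allclose(g_small[k], g_inf[k] - m.params[k], atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_gradient_matches_finite_differences(self, seed):
        """Analytic vs central finite differences, >= 20 random models."""
        rng = np.random.default_rng(seed)
        m = random_model(
            int(rng.integers(2, 4)), int(rng.integers(2, 4)),
            2, int(rng.integers(2, 4)), scale=0.8, seed=seed,
        )
        x = {d: int(rng.integers(2)) for d in m.inputs()}
        y = {o: int(rng.integers(2)) for o in m.outcomes()}
        s2 = 5.0
        g = gradient(m, x, y, sigma2=s2, infer_fn=brute_force_infer)
        h = 1e-5

        def obj():
            pen = sum(float(np.sum(t ** 2)) for t in m.params.values())
            return log_likelihood(m, x, y, infer_fn=brute_force_infer) - pen / (2 * s2)

        for k in m.edge_keys:
            for i in range(2):
                for j in range(2):
                    m.params[k][i, j] += h
                    up = obj()
                    m.params[k][i, j] -= 2 * h
                    dn = obj()
                    m.params[k][i, j] += h
                    assert g[k][i, j] == pytest.approx((up - dn) / (2 * h), abs=1e-4)


class TestTrainPredict:
    def _db(self, model, n=20, seed=0):
        rng = np.random.default_rng(seed)
        db = []
        for _ in range(n):
            x = {d: int(rng.integers(2)) for d in model.inputs()}
            y = {o: int(rng.integers(2)) for o in model.outcomes()}
            db.append((x, y))
        return db

    def test_zero_step_rate_is_noop(self, small_net):
        m = build_model(small_net, init="gaussian", seed=5)
        before = {k: v.copy() for k, v in m.params.items()}
        train(m, self._db(m), alpha=0.0, epochs=2, seed=1)
        for k in before:
            np.testing.assert_array_equal(m.params[k], before[k])

    def test_same_seed_same_training(self, small_net):
        runs = []
        for _ in range(2):
            m = build_model(small_net, init="gaussian", seed=5)
            train(m, self._db(m), alpha=0.05, epochs=2, seed=9)
            runs.append({k: v.copy() for k, v in m.params.items()})
        for k in runs[0]:
            np.testing.assert_array_equal(runs[0][k], runs[1][k])

    def test_empty_db_rejected(self, small_net):
        with pytest.raises(ModelError):
            train(build_model(small_net), [], epochs=1)

    def test_objective_improves_on_tree_model(self, small_net):
        """Full-epoch SGA on exactly inferable (acyclic) models climbs the
        objective when the data come from a structured ground truth."""
        from adrnet.synthetic import sample_reports
        from adrnet.pharmacovigilance import map_labels, vectorize
        from adrnet.synthetic import gen_model

        truth = gen_model(small_net, 1.2, seed=4, style="interaction")
        db = sample_reports(truth, 150, 0.5, seed=6)
        mdb, _ = map_labels(db, small_net)
        m = build_model(small_net, init="gaussian", init_scale=0.2, seed=8)
        vecs = vectorize(mdb, m)
        _, trace = train(m, vecs, alpha=0.02, epochs=4, seed=2)
        assert trace[-1] > trace[0]

    def test_predict_uniform_at_zero(self, small_net):
        m = build_model(small_net, init="zero")
        probs = predict(m, {d: 1 for d in m.inputs()})
        assert set(probs) == set(m.outcomes())
        assert all(p == pytest.approx(0.5, abs=1e-12) for p in probs.values())

    def test_predict_matches_brute_force_on_trees(self, small_net):
        m = build_model(small_net, init="gaussian", seed=11)
        x = {d: 1 for d in m.inputs()}
        got = predict(m, x)
        want = predict(m, x, infer_fn=brute_force_infer)
        for o in got:
            assert got[o] == pytest.approx(want[o], abs=1e-9)

    def test_disconnected_outcome_ignores_inputs(self):
        net = make_net(
            [("d1", "E1"), ("p1", "E2"), ("w1", "E3"), ("a1", "E4"), ("a2", "E4")],
            [("R1", "d1", "p1"), ("R4", "p1", "w1"), ("R5", "w1", "a1")],
        )
        m = build_model(net, init="gaussian", seed=3)
        p1 = predict(m, {"d1": 1})["a2"]
        p0 = predict(m, {"d1": 0})["a2"]
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, small_net):
        m = build_model(small_net, init="gaussian", seed=6)
        text = m.to_json(meta={"alpha": 0.01})
        back = HCRFModel.from_json(text)
        x = {d: 1 for d in m.inputs()}
        assert predict(back, x) == predict(m, x)
        assert back.to_json(meta={"alpha": 0.01}) == text


class TestLearningApproachesBayesCeiling:
    def test_trained_model_matches_bayes_scores(self):
        """With symmetry-breaking init and a signal-bearing ground truth,
        SGA-trained predictions should rank held-out reports as well as the
        ground-truth model itself (within a small AUROC margin)."""
        from adrnet.pharmacovigilance import auroc, map_labels, vectorize
        from adrnet.synthetic import gen_model, sample_reports

        net = make_net(
            [("d1", "E1"), ("d2", "E1"), ("d3", "E1"), ("p1", "E2"), ("p2", "E2"),
             ("w1", "E3"), ("w2", "E3"), ("a1", "E4"), ("a2", "E4")],
            [("R1", "d1", "p1"), ("R1", "d2", "p1"), ("R1", "d3", "p2"),
             ("R4", "p1", "w1"), ("R4", "p2", "w2"),
             ("R5", "w1", "a1"), ("R5", "w2", "a2")],
        )
        truth = gen_model(net, 1.5, seed=21, style="interaction")
        train_db, _ = map_labels(sample_reports(truth, 1200, 0.5, seed=22), net)
        held_db, _ = map_labels(sample_reports(truth, 500, 0.5, seed=23), net)

        m = build_model(net, init="gaussian", init_scale=0.5, seed=24)
        vecs = vectorize(train_db, m)
        train(m, vecs, alpha=0.05, epochs=5, seed=25, eval_objective=False)

        hv = vectorize(held_db, m)
        cache_t, cache_m = {}, {}
        for o in m.outcomes():
            st, sm, lab = [], [], []
            for x, y in hv:
                key = tuple(sorted(x.items()))
                if key not in cache_t:
                    cache_t[key] = predict(truth, x)
                    cache_m[key] = predict(m, x)
                st.append(cache_t[key][o])
                sm.append(cache_m[key][o])
                lab.append(y[o])
            bayes = auroc(st, lab)
            learned = auroc(sm, lab)
            assert learned > 0.75
            assert learned >= bayes - 0.05
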