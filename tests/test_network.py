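"""Exactness and oracle tests for the hierarchical survival network."""

import numpy as np
import pandas as pd
import pytest

from bfreg.autodiff import Tensor
from bfreg.hierarchy import BioHierarchy
from bfreg.network import (
    ALPHA_UNKNOWN_EDGE,
    BFRegNN,
    TrainConfig,
    concordance_index,
    cox_loss,
    integrated_gradients,
    train_model,
)
from bfreg.synthetic import gen_cohort, gen_hierarchy


def _toy_hierarchy():
    """3 genes -> 2 proteins -> 1 pathway -> survival, hand-wired."""
    nodes = {"gene": ["g0", "g1", "g2"], "protein": ["p0", "p1"],
             "pathway": ["w0"], "survival": ["survival"]}
    adjacency = {
        "gene": np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], float),
        "protein": np.zeros((2, 2)),
        "pathway": np.zeros((1, 1)),
        "survival": np.zeros((1, 1)),
    }
    maps = {
        "gene": np.array([[1, 1, 0], [0, 0, 1]], float),   # g2 -> p1 only
        "protein": np.array([[1, 1.0]]),
        "pathway": np.ones((1, 1)),
    }
    return BioHierarchy(nodes=nodes, adjacency=adjacency, maps=maps)


def _numpy_forward(net, x):
    """Independent straight-line evaluation of the network, no autodiff."""

    def act(v):
        name = net.activation_name
        if name == "logistic":
            return 1 / (1 + np.exp(-v))
        if name == "identity":
            return v
        if name == "mix":
            return 0.5 * v + 0.5 / (1 + np.exp(-v))
        raise ValueError(name)

    P = {k: t.data for k, t in net.params.items()}
    H = x[:, :, None] * P["emb"][None]
    for lvl in ("gene", "protein", "pathway"):
        A = net.hierarchy.adjacency[lvl]
        for _ in range(net.rounds):
            if lvl in net.learnable_levels:
                b, n, d = H.shape
                scale = A + ALPHA_UNKNOWN_EDGE * (1 - A)
                pair = np.concatenate(
                    [np.broadcast_to(H[:, :, None, :], (b, n, n, d)),
                     np.broadcast_to(H[:, None, :, :], (b, n, n, d))], axis=-1)
                hid = np.tanh(pair @ P[f"adj_W1_{lvl}"] + P[f"adj_b1_{lvl}"])
                beta = (hid @ P[f"adj_W2_{lvl}"] + P[f"adj_b2_{lvl}"])[..., 0]
                msgs = (beta * scale) @ H
            else:
                msgs = A @ H
            H = act(P[f"w_self_{lvl}"] * H + P[f"w_msg_{lvl}"] * msgs)
        eff = P[f"W_{lvl}"] * net.hierarchy.maps[lvl]
        H = act(eff @ H + P[f"b_{lvl}"][None, :, None])
    return H[:, 0, :] @ P["w_out"] + P["b_out"]


@pytest.fixture(scope="module")
def toy_net():
    return BFRegNN(_toy_hierarchy(), dim=2, learnable_adjacency=("gene",), seed=5)


class TestEmbeddings:
    def test_zero_input_zero_embedding(self, toy_net):
        H = toy_net.init_embeddings(np.zeros((1, 3)))
        assert np.all(H.data == 0)

    def test_homogeneity(self, toy_net):
        x = np.array([[1.0, -2.0, 0.5]])
        assert np.allclose(toy_net.init_embeddings(2 * x).data,
                           2 * toy_net.init_embeddings(x).data)

    def test_matches_hand_computation(self, toy_net):
        x = np.array([[1.5, -1.0, 2.0]])
        H = toy_net.init_embeddings(x)
        expected = x[0][:, None] * toy_net.params["emb"].data
        assert np.allclose(H.data, expected, atol=1e-12)


class TestIntraLevelMessagePassing:
    def test_empty_adjacency_is_pure_self_update(self, toy_net):
        # protein level has no edges: output = sigma(w_self * H)
        H = Tensor(np.random.default_rng(1).normal(size=(2, 2, 2)))
        out = toy_net.message_pass_intra(H, "protein")
        w = toy_net.params["w_self_protein"].data
        assert np.allclose(out.data, 1 / (1 + np.exp(-w * H.data)), atol=1e-12)

    def test_two_node_scalar_hand_computation(self):
        nodes = {"gene": ["a", "b"], "protein": ["p"], "pathway": ["w"],
                 "survival": ["survival"]}
        bh = BioHierarchy(
            nodes=nodes,
            adjacency={"gene": np.array([[0, 1], [1, 0]], float),
                       "protein": np.zeros((1, 1)), "pathway": np.zeros((1, 1)),
                       "survival": np.zeros((1, 1))},
            maps={"gene": np.ones((1, 2)), "protein": np.ones((1, 1)),
                  "pathway": np.ones((1, 1))},
        )
        net = BFRegNN(bh, dim=1, learnable_adjacency=(), seed=0)
        net.params["w_self_gene"].data = np.asarray(0.7)
        net.params["w_msg_gene"].data = np.asarray(0.3)
        H = Tensor(np.array([[[2.0], [-1.0]]]))
        out = net.message_pass_intra(H, "gene")
        expected = 1 / (1 + np.exp(-np.array([[0.7 * 2 + 0.3 * (-1)],
                                              [0.7 * (-1) + 0.3 * 2]])))
        assert np.allclose(out.data[0], expected, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        n = 5
        A = (rng.uniform(size=(n, n)) < 0.4).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        perm = rng.permutation(n)
        nodes = lambda ids: {"gene": ids, "protein": ["p"], "pathway": ["w"],
                             "survival": ["survival"]}
        base = {"protein": np.zeros((1, 1)), "pathway": np.zeros((1, 1)),
                "survival": np.zeros((1, 1))}
        maps = {"gene": np.ones((1, n)), "protein": np.ones((1, 1)),
                "pathway": np.ones((1, 1))}
        bh1 = BioHierarchy(nodes=nodes([f"g{i}" for i in range(n)]),
                           adjacency={"gene": A, **base}, maps=maps)
        bh2 = BioHierarchy(nodes=nodes([f"g{i}" for i in range(n)]),
                           adjacency={"gene": A[np.ix_(perm, perm)], **base}, maps=maps)
        net1 = BFRegNN(bh1, dim=3, learnable_adjacency=(), seed=1)
        net2 = BFRegNN(bh2, dim=3, learnable_adjacency=(), seed=1)
        for k in ("w_self_gene", "w_msg_gene"):
            net2.params[k].data = net1.params[k].data
        H = np.random.default_rng(4).normal(size=(2, n, 3))
        out1 = net1.message_pass_intra(Tensor(H), "gene").data
        out2 = net2.message_pass_intra(Tensor(H[:, perm, :]), "gene").data
        assert np.allclose(out2, out1[:, perm, :], atol=1e-12)


class TestCrossLevelPropagation:
    def test_all_zero_map_gives_sigma_bias(self, toy_net):
        net = BFRegNN(_toy_hierarchy(), dim=2, learnable_adjacency=(), seed=5)
        net.hierarchy.maps["gene"] = np.zeros((2, 3))
        H = Tensor(np.random.default_rng(0).normal(size=(4, 3, 2)))
        out = net.propagate_cross_level(H, "gene")
        b = net.params["b_gene"].data
        expected = 1 / (1 + np.exp(-b))[None, :, None] * np.ones((4, 2, 2))
        assert np.allclose(out.data, expected, atol=1e-12)
        net.hierarchy.maps["gene"] = np.array([[1, 1, 0], [0, 0, 1]], float)

    def test_masked_weight_perturbation_is_invisible(self, toy_net):
        x = np.random.default_rng(2).normal(size=(3, 3))
        before = toy_net.predict(x)
        W = toy_net.params["W_gene"].data
        M = toy_net.hierarchy.maps["gene"]
        assert M[0, 2] == 0
        W[0, 2] += 123.456          # masked position: must not matter
        after = toy_net.predict(x)
        assert np.array_equal(before, after)
        W[0, 2] -= 123.456

    def test_two_to_three_node_logistic_hand_computation(self):
        nodes = {"gene": ["a", "b"], "protein": ["p0", "p1", "p2"],
                 "pathway": ["w"], "survival": ["survival"]}
        bh = BioHierarchy(
            nodes=nodes,
            adjacency={"gene": np.zeros((2, 2)), "protein": np.zeros((3, 3)),
                       "pathway": np.zeros((1, 1)), "survival": np.zeros((1, 1))},
            maps={"gene": np.array([[1, 0], [1, 1], [0, 1.0]]),
                  "protein": np.ones((1, 3)), "pathway": np.ones((1, 1))},
        )
        net = BFRegNN(bh, dim=1, learnable_adjacency=(), seed=0)
        W = np.array([[0.5, 9.9], [-0.2, 0.4], [9.9, 0.8]])
        b = np.array([0.1, -0.3, 0.2])
        net.params["W_gene"].data = W
        net.params["b_gene"].data = b
        H = np.array([[[1.0], [2.0]]])
        out = net.propagate_cross_level(Tensor(H), "gene")
        eff = W * bh.maps["gene"]
        expected = 1 / (1 + np.exp(-(eff @ H[0] + b[:, None])))
        assert np.allclose(out.data[0], expected, atol=1e-12)


class TestLearnableAdjacency:
    def _one_pair_net(self):
        nodes = {"gene": ["a", "b"], "protein": ["p"], "pathway": ["w"],
                 "survival": ["survival"]}
        bh = BioHierarchy(
            nodes=nodes,
            adjacency={"gene": np.array([[0, 1], [0, 0.0]]),
                       "protein": np.zeros((1, 1)), "pathway": np.zeros((1, 1)),
                       "survival": np.zeros((1, 1))},
            maps={"gene": np.ones((1, 2)), "protein": np.ones((1, 1)),
                  "pathway": np.ones((1, 1))},
        )
        return BFRegNN(bh, dim=1, learnable_adjacency=("gene",), seed=0)

    def test_known_and_unknown_edge_scaling(self):
        net = self._one_pair_net()
        # force the pair MLP to output beta = 0.8 for every pair
        net.params["adj_W1_gene"].data[:] = 0.0
        net.params["adj_b1_gene"].data[:] = 0.0
        net.params["adj_W2_gene"].data[:] = 0.0
        net.params["adj_b2_gene"].data[:] = 0.8
        H = Tensor(np.ones((1, 2, 1)))
        eff = net.learnable_adjacency_weights(H, "gene").data[0]
        assert eff[0, 1] == pytest.approx(0.8, abs=1e-12)      # known edge
        assert eff[1, 0] == pytest.approx(0.004, abs=1e-12)    # 0.005 * 0.8
        assert eff[0, 0] == pytest.approx(0.004, abs=1e-12)

    def test_mlp_matches_hand_computation(self):
        net = self._one_pair_net()
        rng = np.random.default_rng(9)
        W1 = rng.normal(size=(2, 3))
        b1 = rng.normal(size=3)
        W2 = rng.normal(size=(3, 1))
        b2 = rng.normal(size=1)
        net.params["adj_W1_gene"].data = W1
        net.params["adj_b1_gene"].data = b1
        net.params["adj_W2_gene"].data = W2
        net.params["adj_b2_gene"].data = b2
        net.mlp_hidden = 3
        H = rng.normal(size=(1, 2, 1))
        eff = net.learnable_adjacency_weights(Tensor(H), "gene").data[0]
        A = net.hierarchy.adjacency["gene"]
        for i in range(2):
            for j in range(2):
                pair = np.r_[H[0, i], H[0, j]]
                beta = np.tanh(pair @ W1 + b1) @ W2 + b2
                scale = 1.0 if A[i, j] == 1 else ALPHA_UNKNOWN_EDGE
                assert eff[i, j] == pytest.approx(beta.item() * scale, abs=1e-10)


class TestForward:
    @pytest.mark.parametrize("learnable", [(), ("gene",)])
    def test_matches_straight_line_numpy_oracle(self, learnable):
        hier = gen_hierarchy(6, 4, 2, edge_density=0.4, n_modules=1,
                             module_size=3, seed=8)
        bh = BioHierarchy.from_true_hierarchy(hier)
        net = BFRegNN(bh, dim=3, rounds_per_level=2,
                      learnable_adjacency=learnable, seed=11)
        x = np.random.default_rng(12).normal(size=(5, 6))
        assert np.allclose(net.predict(x), _numpy_forward(net, x), atol=1e-10)

    def test_zero_inputs_give_bias_only_value(self, toy_net):
        scores = toy_net.predict(np.zeros((2, 3)))
        expected = _numpy_forward(toy_net, np.zeros((2, 3)))
        assert np.allclose(scores, expected, atol=1e-12)
        assert scores[0] == pytest.approx(scores[1], abs=1e-15)

    def test_gene_without_path_to_survival_is_ignored(self):
        bh = _toy_hierarchy()
        bh.maps["gene"][:, 2] = 0          # cut g2 off from the protein level
        net = BFRegNN(bh, dim=2, learnable_adjacency=(), seed=5)
        x = np.array([[1.0, 2.0, 3.0]])
        x2 = np.array([[1.0, 2.0, -7.0]])
        # g2 also has no gene-level edges, so its expression cannot matter
        assert np.array_equal(net.predict(x), net.predict(x2))

    def test_wrong_input_width_rejected(self, toy_net):
        with pytest.raises(ValueError, match="expected inputs"):
            toy_net.predict(np.zeros((1, 4)))


class TestCoxLoss:
    def test_closed_form_at_zero_scores(self):
        time = np.array([3.0, 1.0, 2.0, 5.0])
        event = np.array([1, 1, 0, 1])
        loss = cox_loss(np.zeros(4), time, event)
        sizes = [(time >= t).sum() for t in time[event == 1]]
        assert loss.item() == pytest.approx(sum(np.log(s) for s in sizes), abs=1e-12)

    def test_two_subject_direct_evaluation(self):
        loss = cox_loss(np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([1, 1]))
        expected = -(1.0 - np.log(np.exp(1.0) + np.exp(0.0))) - (0.0 - 0.0)
        assert loss.item() == pytest.approx(expected, abs=1e-12)

    def test_shift_invariance(self, rng):
        s = rng.normal(size=30)
        t = rng.uniform(1, 10, size=30)
        e = (rng.uniform(size=30) < 0.7).astype(int)
        l1 = cox_loss(s, t, e).item()
        l2 = cox_loss(s + 100.0, t, e).item()
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            cox_loss(np.zeros(3), np.ones(3), np.zeros(3, int))

    def test_gradient_vanishes_at_cox_fit_optimum(self):
        # cross-module consistency: at H = X beta-hat from the Newton-Raphson
        # fit, the loss gradient with respect to beta is ~ 0
        from bfreg.screen import cox_fit
        from bfreg.synthetic import standardized_log_expression
        cohort = gen_cohort(120, 10, 4, n_prognostic=2,
                            effect_sizes={"beta": [0.8, -0.6]}, seed=13)
        Z = standardized_log_expression(cohort).T
        model = cox_fit(cohort.survival, Z)
        beta = Tensor(model.beta.values, requires_grad=True)
        H = Tensor(Z[model.covariates].values) @ beta
        loss = cox_loss(H, cohort.survival["time"].values,
                        cohort.survival["event"].values)
        loss.backward()
        assert np.max(np.abs(beta.grad)) < 1e-6


class TestConcordance:
    @staticmethod
    def _brute_force(scores, time, event):
        num = den = 0.0
        n = len(scores)
        for i in range(n):
            for j in range(n):
                if time[i] < time[j] and event[i] == 1:
                    den += 1
                    if scores[i] > scores[j]:
                        num += 1
                    elif scores[i] == scores[j]:
                        num += 0.5
        return num / den

    def test_perfectly_anti_ordered_scores(self):
        t = np.array([1.0, 2, 3, 4])
        assert concordance_index(-t, t, np.ones(4, int)) == 1.0

    def test_identical_scores_half(self):
        t = np.array([1.0, 2, 3, 4])
        assert concordance_index(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_censored_fixture_matches_brute_force(self):
        s = np.array([0.3, -1.2, 0.8, 0.8, 0.0, 2.0])
        t = np.array([5.0, 3.0, 9.0, 2.0, 7.0, 2.0])
        e = np.array([1, 0, 1, 1, 0, 0])
        assert concordance_index(s, t, e) == self._brute_force(s, t, e)

    def test_hundred_random_fixtures_match_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            s = rng.normal(size=n).round(1)       # rounded to force score ties
            t = rng.integers(1, 6, size=n).astype(float)
            e = (rng.uniform(size=n) < 0.7).astype(int)
            if not ((t[:, None] > t[None, :]) & (e[None, :] == 1)).any():
                continue
            assert concordance_index(s, t, e) == self._brute_force(s, t, e)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index(np.zeros(3), np.ones(3), np.zeros(3, int))


class TestIntegratedGradients:
    def test_linear_model_exact_at_any_steps(self):
        # an identity-activation net IS linear in its inputs, so IG must be
        # exact even at steps=1
        hier = gen_hierarchy(5, 4, 2, module_size=3, seed=2)
        bh = BioHierarchy.from_true_hierarchy(hier)
        net = BFRegNN(bh, dim=2, activation="identity",
                      learnable_adjacency=(), seed=3)
        x = np.random.default_rng(1).normal(size=5)
        x0 = np.zeros(5)
        ig1 = integrated_gradients(net, x, x0, steps=1)
        ig64 = integrated_gradients(net, x, x0, steps=64)
        assert np.allclose(ig1, ig64, atol=1e-10)
        assert np.sum(ig1) == pytest.approx(
            float(net.predict(x[None])[0] - net.predict(x0[None])[0]), abs=1e-10)

    def test_baseline_equals_input_gives_zero(self, toy_net):
        x = np.array([1.0, 2.0, 3.0])
        assert np.allclose(integrated_gradients(toy_net, x, x, steps=8), 0.0)

    def test_completeness_at_512_steps(self):
        hier = gen_hierarchy(8, 5, 2, edge_density=0.3, module_size=4, seed=4)
        bh = BioHierarchy.from_true_hierarchy(hier)
        net = BFRegNN(bh, dim=4, seed=6)
        rng = np.random.default_rng(7)
        x, x0 = rng.normal(size=8), rng.normal(size=8)
        ig = integrated_gradients(net, x, x0, steps=512)
        gap = float(net.predict(x[None])[0] - net.predict(x0[None])[0])
        assert abs(ig.sum() - gap) < 1e-3


class TestTraining:
    def test_same_seed_identical_traces(self, small_bio_hierarchy, small_cohort):
        cfg = TrainConfig(max_epochs=3, seed=5, dim=4)
        r1 = train_model(small_bio_hierarchy, small_cohort, cfg).report
        r2 = train_model(small_bio_hierarchy, small_cohort, cfg).report
        assert r1["history"]["train_loss"] == r2["history"]["train_loss"]
        assert r1["history"]["val_loss"] == r2["history"]["val_loss"]

    def test_null_signal_cindex_near_half(self):
        hier = gen_hierarchy(20, 12, 4, seed=3)
        bh = BioHierarchy.from_true_hierarchy(hier)
        cohort = gen_cohort(300, 20, 20, n_prognostic=0, seed=3)
        cfg = TrainConfig(max_epochs=10, seed=3, dim=8)
        model = train_model(bh, cohort, cfg)
        assert abs(model.report["val_cindex"] - 0.5) <= 0.1

    def test_invalid_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(train_fraction=1.0)

    def test_attribution_recovers_planted_module(self, default_study):
        # top-10 integrated-gradient genes overlap the planted prognostic
        # module with Jaccard >= 0.5 on the default trained study
        hier, _, cohort, model = default_study
        x = model.transform(cohort.expression[cohort.tumor_samples]).mean(axis=0)
        ig = integrated_gradients(model.net, x, np.zeros_like(x), steps=64)
        attr = pd.Series(ig, index=model.gene_ids)
        top10 = set(attr.abs().nlargest(10).index)
        module = set(hier.planted_modules[0])
        assert len(top10 & module) / len(top10 | module) >= 0.5
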