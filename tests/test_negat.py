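"""Attention network: primitives vs oracles, invariances, training."""

import numpy as np
import pytest

from metaconn.linkgraph import LinkGraph
from metaconn.negat import (
    NEGATConfig,
    NEGATParams,
    _forward_graph,
    _PreparedGraph,
    attention_coefficients,
    compute_loss,
    fit,
    forward,
    predict,
    propagate,
    smooth_labels,
    transform_features,
)


def tiny_cfg(**kw):
    defaults = dict(depth=2, node_hidden=4, edge_hidden=3, final_hidden=5,
                    mlp_hidden=4, dropout=0.0, seed=0)
    defaults.update(kw)
    return NEGATConfig(**defaults)


def random_graph(rng, n=8, p=0.4, node_dim=3, edge_dim=2, label=0):
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
    if not pairs:
        pairs = [(0, 1)]
    edges = np.array(pairs)
    return LinkGraph(
        n_nodes=n,
        node_features=rng.normal(size=(n, node_dim)),
        edges=edges,
        edge_features=rng.normal(size=(len(edges), edge_dim)),
        label=label,
    )


class TestPrimitives:
    def test_identity_transform_passes_features_through(self, rng):
        cfg = tiny_cfg(node_hidden=3, edge_hidden=2)
        params = NEGATParams.init(3, 2, cfg, rng)
        params["W_node0"] = np.eye(3)
        params["W_edge"] = np.eye(2)
        h = rng.normal(size=(5, 3))
        e = rng.normal(size=(4, 2))
        hp, ep = transform_features(h, e, params)
        assert np.array_equal(hp, h) and np.array_equal(ep, e)

    def test_zero_input_maps_to_zero(self, rng):
        params = NEGATParams.init(3, 2, tiny_cfg(), rng)
        hp, ep = transform_features(np.zeros((2, 3)), np.zeros((1, 2)), params)
        assert not hp.any() and not ep.any()

    def test_matrix_vector_oracle(self, rng):
        w = rng.normal(size=(3, 2))
        params = NEGATParams.init(2, 2, tiny_cfg(node_hidden=3), rng)
        params["W_node0"] = w
        h = rng.normal(size=(1, 2))
        hp, _ = transform_features(h, np.zeros((1, 2)), params)
        manual = [sum(w[r, c] * h[0, c] for c in range(2)) for r in range(3)]
        assert np.allclose(hp[0], manual, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        params = NEGATParams.init(3, 2, tiny_cfg(), rng)
        with pytest.raises(ValueError):
            transform_features(np.zeros((2, 4)), np.zeros((1, 2)), params)


class TestAttention:
    def test_single_neighbor_gets_full_weight(self, rng):
        a = attention_coefficients(
            rng.normal(size=(1, 4)), rng.normal(size=4), rng.normal(size=4),
            kind="node", self_feat=rng.normal(size=4),
        )
        assert a[0] == pytest.approx(1.0)

    def test_identical_neighbors_share_weight_equally(self, rng):
        nb = np.tile(rng.normal(size=4), (2, 1))
        a = attention_coefficients(nb, rng.normal(size=4), rng.normal(size=4),
                                   kind="node", self_feat=rng.normal(size=4))
        assert np.allclose(a, [0.5, 0.5])

    def test_matches_softmax_oracle(self, rng):
        a_src, a_dst = rng.normal(size=4), rng.normal(size=4)
        hi = rng.normal(size=4)
        nb = rng.normal(size=(5, 4))
        got = attention_coefficients(nb, a_src, a_dst, kind="node", self_feat=hi)
        slope = 0.2
        raw = [a_src @ hi + a_dst @ h for h in nb]
        act = [x if x > 0 else slope * x for x in raw]
        ex = np.exp(act)
        assert np.abs(got - ex / ex.sum()).max() < 1e-10
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_edge_kind_scores_each_edge_by_its_own_feature(self, rng):
        a_src, a_dst = rng.normal(size=3), rng.normal(size=3)
        incident = rng.normal(size=(4, 3))
        got = attention_coefficients(incident, a_src, a_dst, kind="edge")
        raw = incident @ (a_src + a_dst)
        act = np.where(raw > 0, raw, 0.2 * raw)
        ex = np.exp(act)
        assert np.abs(got - ex / ex.sum()).max() < 1e-10

    def test_empty_neighborhood_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            attention_coefficients(np.empty((0, 3)), np.zeros(3), np.zeros(3),
                                   kind="edge")


class TestPropagate:
    def test_single_neighbor_copies_its_feature(self, rng):
        hp = rng.normal(size=(2, 3))
        h2, _ = propagate(hp, None, [np.array([1]), np.array([0])],
                          [np.array([1.0]), np.array([1.0])])
        assert np.allclose(h2[0], hp[1]) and np.allclose(h2[1], hp[0])

    def test_uniform_weights_average_neighbors(self, rng):
        hp = rng.normal(size=(4, 3))
        nbrs = [np.array([1, 2, 3])] + [np.array([0])] * 3
        alpha = [np.full(3, 1 / 3)] + [np.array([1.0])] * 3
        h2, _ = propagate(hp, None, nbrs, alpha)
        assert np.allclose(h2[0], hp[1:].mean(axis=0))

    def test_matches_loop_oracle(self, rng):
        n = 6
        hp = rng.normal(size=(n, 4))
        nbrs = [np.array([j for j in range(n) if j != i and (i + j) % 2])
                for i in range(n)]
        alpha = []
        for nb in nbrs:
            if len(nb):
                w = rng.random(len(nb))
                alpha.append(w / w.sum())
            else:
                alpha.append(np.array([]))
        h2, _ = propagate(hp, None, nbrs, alpha)
        for i in range(n):
            if len(nbrs[i]) == 0:
                expect = hp[i]
            else:
                expect = np.zeros(4)
                for w, j in zip(alpha[i], nbrs[i]):
                    expect = expect + w * hp[j]
            assert np.abs(h2[i] - expect).max() < 1e-10


class TestLabelsAndLoss:
    def test_label_smoothing_example(self):
        assert np.allclose(smooth_labels(np.array([1.0, 0.0]), 0.1, 2), [0.95, 0.05])

    def test_zero_alpha_is_identity(self):
        y = np.array([0.0, 1.0])
        assert np.array_equal(smooth_labels(y, 0.0, 2), y)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.5])
    def test_probability_mass_conserved(self, alpha):
        y = np.eye(3)
        assert np.allclose(smooth_labels(y, alpha, 3).sum(axis=1), 1.0)

    def test_loss_at_target_equals_entropy(self):
        y = smooth_labels(np.array([1.0, 0.0]), 0.1, 2)
        ce = compute_loss(y, y, None, 0.0)
        entropy = -(y * np.log(y)).sum()
        assert ce == pytest.approx(entropy)

    def test_perfect_prediction_zero_loss(self):
        assert compute_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]), None, 0.0) == 0.0

    def test_matches_scalar_formula_oracle(self, rng):
        cfg = tiny_cfg()
        params = NEGATParams.init(3, 2, cfg, rng)
        y = smooth_labels(np.array([0.0, 1.0]), 0.1, 2)
        p = np.array([0.3, 0.7])
        beta = 1e-3
        got = compute_loss(y, p, params, beta)
        expect = sum(-yk * np.log(pk) for yk, pk in zip(y, p))
        for k in params.weight_names():
            expect += beta * float((params[k] ** 2).sum())
        assert abs(got - expect) < 1e-10

    def test_zero_probability_clamped(self):
        val = compute_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0]), None, 0.0)
        assert np.isfinite(val) and val > 0

    def test_cross_entropy_lower_bounded_by_entropy(self, rng):
        y = smooth_labels(np.array([1.0, 0.0]), 0.2, 2)
        entropy = -(y * np.log(y)).sum()
        for _ in range(20):
            p = rng.dirichlet([1, 1])
            assert compute_loss(y, p, None, 0.0) >= entropy - 1e-12


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        g = random_graph(rng)
        cfg = tiny_cfg()
        params = NEGATParams.init(3, 2, cfg, rng)
        pred = forward(g, params, cfg)
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(pred.probabilities >= 0)

    def test_eval_mode_deterministic(self, rng):
        g = random_graph(rng)
        cfg = tiny_cfg(dropout=0.2)
        params = NEGATParams.init(3, 2, cfg, rng)
        p1 = forward(g, params, cfg).probabilities
        p2 = forward(g, params, cfg).probabilities
        assert np.array_equal(p1, p2)

    def test_node_relabeling_invariance(self, rng):
        g = random_graph(rng, n=10, p=0.35)
        cfg = tiny_cfg()
        params = NEGATParams.init(3, 2, cfg, rng)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        edges_p = np.sort(inv[g.edges], axis=1)
        order = np.lexsort((edges_p[:, 1], edges_p[:, 0]))
        g_perm = LinkGraph(
            n_nodes=10,
            node_features=g.node_features[perm],
            edges=edges_p[order],
            edge_features=g.edge_features[order],
        )
        p1 = forward(g, params, cfg).probabilities
        p2 = forward(g_perm, params, cfg).probabilities
        assert np.abs(p1 - p2).max() < 1e-8

    def test_attention_rows_sum_to_one(self, rng):
        g = random_graph(rng, n=12, p=0.3)
        cfg = tiny_cfg()
        params = NEGATParams.init(3, 2, cfg, rng)
        pg = _PreparedGraph(g)
        _, cache = _forward_graph(pg, params, cfg)
        for layer in cache["layers"]:
            sums = pg.segment_sum(layer["alpha"])
            assert np.abs(sums[pg.seg_nodes] - 1.0).max() < 1e-6
        sums = pg.segment_sum(cache["edge"]["alpha"])
        assert np.abs(sums[pg.seg_nodes] - 1.0).max() < 1e-6

    def test_isolated_node_keeps_transformed_feature(self, rng):
        g = LinkGraph(
            n_nodes=3, node_features=rng.normal(size=(3, 3)),
            edges=np.array([[0, 1]]), edge_features=rng.normal(size=(1, 2)),
        )
        cfg = tiny_cfg(depth=1)
        params = NEGATParams.init(3, 2, cfg, rng)
        pg = _PreparedGraph(g)
        _, cache = _forward_graph(pg, params, cfg)
        xp = cache["layers"][0]["xp"]
        assert pg.isolated[2]
        assert np.allclose(cache["hcat"][2, : cfg.node_hidden], xp[2])

    def test_tie_breaks_to_class_zero(self, rng):
        g = random_graph(rng)
        cfg = tiny_cfg()
        params = NEGATParams.init(3, 2, cfg, rng)
        for k in params:
            params[k] = np.zeros_like(params[k])
        pred = forward(g, params, cfg)
        assert np.allclose(pred.probabilities, 0.5)
        assert pred.label == 0


class TestFitPredict:
    def test_single_class_rejected(self, rng):
        graphs = [random_graph(rng, label=1) for _ in range(4)]
        with pytest.raises(ValueError, match="single class"):
            fit(graphs, [1, 1, 1, 1], tiny_cfg(epochs=1))

    def test_same_seed_identical_parameters(self, rng):
        graphs = [random_graph(rng, label=i % 2) for i in range(8)]
        y = [g.label for g in graphs]
        cfg = tiny_cfg(epochs=5, learning_rate=1e-3)
        p1, _ = fit(graphs, y, cfg)
        p2, _ = fit(graphs, y, cfg)
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_loss_decreases_and_overfits_separable_cohort(self, small_graphs):
        graphs, y = small_graphs
        cfg = NEGATConfig(learning_rate=1e-3, epochs=120, node_hidden=16,
                          edge_hidden=16, final_hidden=32, mlp_hidden=16, seed=0)
        params, report = fit(graphs, y, cfg)
        assert report.epoch_loss[-1] < report.epoch_loss[0]
        preds = predict(graphs, params, cfg)
        train_acc = np.mean([p.label for p in preds] == y)
        assert train_acc >= 0.95

    def test_checkpoint_round_trip(self, rng, tmp_path):
        from metaconn.negat import load_checkpoint, save_checkpoint

        graphs = [random_graph(rng, label=i % 2) for i in range(6)]
        cfg = tiny_cfg(epochs=2)
        params, _ = fit(graphs, [g.label for g in graphs], cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg)
        params2, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        assert all(np.array_equal(params[k], params2[k]) for k in params)
        p1 = predict(graphs, params, cfg)[0].probabilities
        p2 = predict(graphs, params2, cfg2)[0].probabilities
        assert np.array_equal(p1, p2)

    def test_predict_dimension_mismatch_rejected(self, rng):
        graphs = [random_graph(rng, label=i % 2) for i in range(6)]
        cfg = tiny_cfg(epochs=2)
        params, _ = fit(graphs, [g.label for g in graphs], cfg)
        bad = random_graph(rng, node_dim=5)
        with pytest.raises(ValueError, match="dimension"):
            predict([bad], params, cfg)
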