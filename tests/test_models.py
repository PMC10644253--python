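"""Graph-convolution operators against oracles; architectures; training."""

import numpy as np
import pytest

from vnfc.models import (
    GraphConvLayer,
    ModelSpec,
    NormalizedOperator,
    TrainConfig,
    build_model,
    count_parameters,
    degree_matrix,
    gcn_forward,
    kilo,
    laplacian,
    predict,
    renormalized_operator,
    train,
)


def random_adjacency(rng, m=10):
    A = rng.uniform(0, 1, (m, m))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return A


class TestOperators:
    def test_degree_matrix_examples(self, rng):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(degree_matrix(A), [1.0, 1.0])
        np.testing.assert_array_equal(degree_matrix(np.zeros((3, 3))), 0.0)
        B = random_adjacency(rng)
        expected = [sum(B[i, j] for j in range(10)) for i in range(10)]
        np.testing.assert_allclose(degree_matrix(B), expected, atol=1e-12)

    def test_laplacian_examples(self, rng):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(laplacian(A), [[1.0, -1.0], [-1.0, 1.0]])
        B = random_adjacency(rng)
        L = laplacian(B)
        np.testing.assert_allclose(L @ np.ones(10), 0.0, atol=1e-12)
        eigs = np.linalg.eigvalsh(L)
        assert eigs.min() > -1e-10  # PSD for symmetric non-negative A

    def test_renormalized_two_node_closed_form(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        op = renormalized_operator(A)
        np.testing.assert_array_equal(op.L_sym, [[0.5, 0.5], [0.5, 0.5]])

    def test_renormalized_zero_adjacency_is_identity(self):
        op = renormalized_operator(np.zeros((5, 5)))
        np.testing.assert_array_equal(op.L_sym, np.eye(5))

    def test_renormalized_matches_elementwise_oracle(self, rng):
        A = random_adjacency(rng)
        op = renormalized_operator(A).L_sym
        At = A + np.eye(10)
        d = At.sum(axis=1)
        expected = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                expected[i, j] = At[i, j] / np.sqrt(d[i] * d[j])
        np.testing.assert_allclose(op, expected, atol=1e-12)

    def test_renormalized_spectral_radius_at_most_one(self, rng):
        op = renormalized_operator(random_adjacency(rng)).L_sym
        assert np.max(np.abs(np.linalg.eigvalsh(op))) <= 1.0 + 1e-10

    def test_row_normalised_walk_matrix_rows_sum_to_one(self, rng):
        A = random_adjacency(rng)
        At = A + np.eye(10)
        walk = At / At.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(walk.sum(axis=1), 1.0)

    def test_negative_adjacency_rejected(self):
        with pytest.raises(ValueError):
            renormalized_operator(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestLayerOracle:
    def test_layer_matches_triple_loop(self, rng):
        """sigma(L X W + b) against an explicit summation on small graphs."""
        for m in (3, 5, 6):
            A = random_adjacency(rng, m)
            op = renormalized_operator(A)
            X = rng.standard_normal((m, 4))
            W = rng.standard_normal((4, 3))
            b = rng.standard_normal((m, 3))
            got = GraphConvLayer(W=W, b=b, activation="relu").apply(op, X)
            expected = np.zeros((m, 3))
            for i in range(m):
                for o in range(3):
                    acc = b[i, o]
                    for j in range(m):
                        for f in range(4):
                            acc += op.L_sym[i, j] * X[j, f] * W[f, o]
                    expected[i, o] = max(acc, 0.0)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_hand_computed_path_graph(self):
        # 3-node path, identity activation, hand-set weights
        A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        op = renormalized_operator(A)
        X = np.ones((3, 1))
        W = np.array([[2.0]])
        b = np.zeros((3, 1))
        got = GraphConvLayer(W=W, b=b, activation="identity").apply(op, X)
        expected = 2.0 * (op.L_sym @ np.ones((3, 1)))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_forward_uniform_softmax_with_zero_weights(self):
        m, C = 5, 4
        op = renormalized_operator(np.zeros((m, m)))
        layers = [GraphConvLayer(W=np.zeros((2, 3)), b=np.zeros((m, 3)), activation="identity")]
        probs = gcn_forward(op, np.ones((m, 2)), layers, np.zeros((m * 3, C)), np.zeros(C))
        np.testing.assert_allclose(probs, 1.0 / C)

    def test_batched_forward_matches_reference(self, rng):
        model = build_model("vn_gcn", n_classes=6, m=13, seed=3)
        A = random_adjacency(rng, 13)
        op = renormalized_operator(A)
        batched = model.predict_proba(op.L_sym[None].astype(np.float32))[0]
        reference = gcn_forward(
            op,
            np.ones((13, 32)),
            model.as_reference_layers(),
            model.params["Wd"].astype(float),
            model.params["bd"].astype(float),
        )
        np.testing.assert_allclose(batched, reference, atol=1e-5)


class TestArchitectures:
    @pytest.mark.parametrize(
        "name,flatten,total,breakdown",
        [
            ("vn_gcn", 584, 67965, {"graph_conv_1": 3360, "graph_conv_2": 840, "dense": 63765}),
            ("tinas_gcn", 512, 59757, {"graph_conv_1": 3072, "graph_conv_2": 768, "dense": 55917}),
            ("cnn_fc", 7200, 785229, {"conv_1": 160, "conv_2": 160, "dense": 784909}),
        ],
    )
    def test_layer_shapes_and_parameter_counts(self, name, flatten, total, breakdown):
        model = build_model(name, n_classes=109)
        assert model.flatten_length == flatten
        assert model.parameter_breakdown() == breakdown
        assert count_parameters(model) == total

    def test_reported_kilocounts(self):
        assert kilo(count_parameters(build_model("vn_gcn"))) == 68.0
        assert kilo(count_parameters(build_model("tinas_gcn"))) == 59.8
        assert kilo(count_parameters(build_model("cnn_fc"))) == 785.2

    def test_vn_gcn_layer_output_shapes(self):
        shapes = build_model("vn_gcn").layer_shapes()
        assert shapes["graph_conv_1"] == (73, 32)
        assert shapes["graph_conv_2"] == (73, 8)
        assert shapes["flatten"] == (584, 1)
        assert shapes["dense"] == (109, 1)

    def test_cnn_shape_chain(self):
        shapes = build_model("cnn_fc").layer_shapes()
        assert shapes["conv_1"] == (63, 63, 32)
        assert shapes["pool_1"] == (31, 31, 32)
        assert shapes["conv_2"] == (30, 30, 32)
        assert shapes["pool_2"] == (15, 15, 32)
        assert shapes["flatten"] == (7200, 1)
        assert 7200 == 15 * 15 * 32

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            build_model("resnet")
        with pytest.raises(ValueError):
            ModelSpec(name="mlp", m=8)


def numerical_grad(model, inputs, y, key, idx, eps=1e-5):
    p = model.params[key]
    orig = p.flat[idx]
    p.flat[idx] = orig + eps
    lp, _ = model.loss_and_grads(inputs, y)
    p.flat[idx] = orig - eps
    lm, _ = model.loss_and_grads(inputs, y)
    p.flat[idx] = orig
    return (lp - lm) / (2 * eps)


def randomize_params(model, rng):
    """Move every parameter to a generic float64 point.

    Zero-initialised biases sit exactly on ReLU kinks (pre-activations equal
    the bias when an input patch is all zero), where analytic subgradients
    and central differences legitimately disagree; a random offset makes the
    loss differentiable at the evaluation point almost surely.
    """
    model.params = {
        k: v.astype(np.float64) + 0.05 * rng.standard_normal(v.shape)
        for k, v in model.params.items()
    }


class TestGradients:
    def test_gcn_backprop_matches_numerical(self, rng):
        model = build_model("vn_gcn", n_classes=3, m=9, seed=1)
        randomize_params(model, rng)
        L = np.stack([renormalized_operator(random_adjacency(rng, 9)).L_sym for _ in range(4)])
        y = np.array([0, 1, 2, 1])
        _, grads = model.loss_and_grads(L, y)
        for key in model.params:
            size = min(4, model.params[key].size)
            for idx in rng.choice(model.params[key].size, size=size, replace=False):
                num = numerical_grad(model, L, y, key, idx)
                assert grads[key].flat[idx] == pytest.approx(num, rel=1e-4, abs=1e-7), key

    def test_cnn_backprop_matches_numerical(self, rng):
        model = build_model("cnn_fc", n_classes=3, seed=1)
        randomize_params(model, rng)
        x = rng.uniform(0, 1, (2, 64, 64))
        y = np.array([0, 2])
        _, grads = model.loss_and_grads(x, y)
        for key in model.params:
            for idx in rng.choice(model.params[key].size, size=3, replace=False):
                num = numerical_grad(model, x, y, key, idx)
                assert grads[key].flat[idx] == pytest.approx(num, rel=1e-3, abs=1e-7), key


class TestTraining:
    def make_separable(self, rng, n_per_class=40, m=19):
        """Two classes with disjoint strong adjacency patterns."""
        ops, ys = [], []
        for c in range(2):
            block = np.zeros((m, m))
            lo = 0 if c == 0 else m // 2
            block[lo : lo + 5, lo : lo + 5] = 0.9
            np.fill_diagonal(block, 0.0)
            for _ in range(n_per_class):
                A = block + 0.05 * random_adjacency(rng, m)
                ops.append(renormalized_operator(A).L_sym.astype(np.float32))
                ys.append(c)
        return np.stack(ops), np.array(ys)

    def test_separable_classes_reach_full_training_accuracy(self, rng):
        ops, ys = self.make_separable(rng)
        model = build_model("vn_gcn", n_classes=2, m=19, seed=0)
        history = train(model, ops, ys, TrainConfig(epochs=30, seed=0))
        assert history["accuracy"][-1] == 1.0
        # loss non-increasing in moving average
        loss = np.array(history["loss"])
        head, tail = loss[:5].mean(), loss[-5:].mean()
        assert tail < head

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        ops, ys = self.make_separable(rng, n_per_class=5)
        model = build_model("vn_gcn", n_classes=2, m=19, seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        train(model, ops, ys, TrainConfig(epochs=0))
        for k in before:
            np.testing.assert_array_equal(before[k], model.params[k])

    def test_single_class_rejected(self, rng):
        ops, ys = self.make_separable(rng, n_per_class=5)
        model = build_model("vn_gcn", n_classes=2, m=19, seed=0)
        with pytest.raises(ValueError, match="two classes"):
            train(model, ops, np.zeros_like(ys), TrainConfig(epochs=1))

    def test_training_is_seed_reproducible(self, rng):
        ops, ys = self.make_separable(rng, n_per_class=10)
        outs = []
        for _ in range(2):
            model = build_model("vn_gcn", n_classes=2, m=19, seed=5)
            train(model, ops, ys, TrainConfig(epochs=3, seed=9))
            outs.append({k: v.copy() for k, v in model.params.items()})
        for k in outs[0]:
            np.testing.assert_array_equal(outs[0][k], outs[1][k])

    def test_predict_probabilities_sum_to_one(self, rng):
        ops, _ = self.make_separable(rng, n_per_class=3)
        model = build_model("vn_gcn", n_classes=2, m=19, seed=0)
        labels, probs = predict(model, ops)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert labels.shape == (ops.shape[0],)

    def test_memorizes_training_window_in_separable_case(self, rng):
        ops, ys = self.make_separable(rng, n_per_class=20)
        model = build_model("vn_gcn", n_classes=2, m=19, seed=0)
        train(model, ops, ys, TrainConfig(epochs=30, seed=0))
        labels, _ = predict(model, ops[:1])
        assert labels[0] == ys[0]

    def test_cnn_trains_on_separable_images(self, rng):
        xs, ys = [], []
        for c in range(2):
            for _ in range(15):
                img = 0.1 * rng.uniform(size=(64, 64))
                if c:
                    img[:8, :8] += 0.9
                else:
                    img[40:48, 40:48] += 0.9
                xs.append(img.astype(np.float32))
                ys.append(c)
        xs, ys = np.stack(xs), np.array(ys)
        model = build_model("cnn_fc", n_classes=2, seed=0)
        history = train(model, xs, ys, TrainConfig(epochs=15, batch_size=8, seed=1))
        assert history["accuracy"][-1] >= 0.9
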