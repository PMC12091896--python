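"""The one-hop convolution model: forward algebra, gradients, training."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from agima import (
    ComplexStructure,
    aggregate_nodes,
    build_adjacency_tensor,
    extract_binding_site,
    forward,
    graph_convolve,
    normalize,
    predict_batch,
    train,
)
from agima.model import (
    ModelConfig,
    _backward_pass,
    _forward_pass,
    init_state,
    load_checkpoint,
    save_checkpoint,
)
from agima.pipeline import prepare_dataset, prepare_graph
from agima.structures import Atom
from agima.synthetic import SyntheticTaskSpec, make_labeled_dataset

from conftest import random_site


def nodewise_convolve(F, A_slice, W, activation="relu"):
    """Node-by-node message-passing form: self term 1/D_ii plus neighbor
    terms A_ij / sqrt(D_ii D_jj), the local-update reading of the
    normalized-matrix convolution."""
    n = F.shape[0]
    A_tilde = A_slice.astype(float) + np.eye(n)
    deg = A_tilde.sum(axis=1)
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        acc = (1.0 / deg[i]) * F[i] @ W
        for j in range(n):
            if j != i and A_tilde[i, j]:
                acc = acc + (A_tilde[i, j] / np.sqrt(deg[i] * deg[j])) * F[j] @ W
        out[i] = acc
    return np.maximum(out, 0) if activation == "relu" else np.tanh(out)


class TestGraphConvolve:
    def test_identity_case(self, rng):
        F = rng.normal(size=(5, 3))
        out = graph_convolve(F, np.eye(5), np.eye(3), activation="relu")
        assert np.allclose(out, np.maximum(F, 0))

    def test_zero_features(self, rng):
        N_k = rng.random((4, 4))
        for act in ("relu", "tanh"):
            assert np.allclose(graph_convolve(np.zeros((4, 2)), N_k, np.ones((2, 3)), act), 0)

    def test_matrix_equals_nodewise(self, rng):
        """Matrix convolution equals the node-wise message-passing sum."""
        for _ in range(5):
            site = random_site(rng, n_ligand=3, n_protein=5)
            A = build_adjacency_tensor(site, "AGIMA_2")
            N = normalize(A)
            F = rng.normal(size=(site.n, 4))
            W = rng.normal(size=(4, 6))
            for k in range(2):
                got = graph_convolve(F, N.slices[k], W, "relu")
                want = nodewise_convolve(F, A.slices[:, :, k], W, "relu")
                assert np.max(np.abs(got - want)) < 1e-10

    def test_shape_errors(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            graph_convolve(rng.normal(size=(4, 3)), np.eye(5), np.eye(3))
        with pytest.raises(ValueError, match="shape mismatch"):
            graph_convolve(rng.normal(size=(4, 3)), np.eye(4), np.eye(5))


class TestAggregate:
    def test_single_node(self, rng):
        F_k = rng.normal(size=(1, 7))
        assert np.array_equal(aggregate_nodes(F_k), F_k[0])

    def test_cancellation(self, rng):
        f = rng.normal(size=6)
        assert np.allclose(aggregate_nodes(np.vstack([f, -f])), 0)

    def test_permutation_invariance(self, rng):
        F_k = rng.normal(size=(9, 4))
        perm = rng.permutation(9)
        assert np.allclose(aggregate_nodes(F_k), aggregate_nodes(F_k[perm]))


def tiny_state(seed=0, m=18, conv_dim=4, dense=(6,), activation="tanh"):
    cfg = ModelConfig(conv_dim=conv_dim, dense_dims=dense, dropout_rate=0.0,
                      activation=activation, seed=seed)
    return init_state(cfg, m, np.random.default_rng(seed))


class TestForward:
    def test_closed_form_three_atoms(self):
        """Hand-set weights on a 3-atom graph reproduce the explicit chain."""
        atoms = [
            Atom("C", [0.0, 0.0, 0.0], "ligand", 1),
            Atom("N", [2.5, 0.0, 0.0], "protein", 1),
            Atom("N", [0.0, 3.5, 0.0], "protein", 2),
        ]
        site = extract_binding_site(ComplexStructure("t3", atoms), 4.0)
        N = normalize(build_adjacency_tensor(site, "AGIMA_2"))
        F = np.array([[1.0, 2.0], [0.5, -1.0], [0.0, 1.5]])
        state = tiny_state(m=18)  # overwrite everything below
        state.W_conv = [np.array([[1.0, 0.0], [0.0, 1.0]]) for _ in range(2)]
        state.W_dense = [np.eye(4)]
        state.b_dense = [np.zeros(4)]
        state.w_out = np.array([1.0, -1.0, 0.5, 2.0])
        state.b_out = np.array([0.25])
        state.config.activation = "relu"
        state.config.conv_dim = 2
        y, emb = forward(state, F, N)
        # explicit chain with identity weights and relu
        h = np.concatenate([
            np.maximum(N.slices[0] @ F, 0).sum(axis=0),
            np.maximum(N.slices[1] @ F, 0).sum(axis=0),
        ])
        expected = float(state.w_out @ np.maximum(h, 0) + 0.25)
        assert y == pytest.approx(expected, abs=1e-12)
        assert np.allclose(emb.h, h)

    def test_rigid_motion_invariance(self, rng):
        from conftest import random_complex

        cs = random_complex(rng, n_ligand=4, n_protein=12)
        state = tiny_state(m=18)
        F1, N1 = prepare_graph(cs)
        R = Rotation.random(random_state=11).as_matrix()
        moved = ComplexStructure(
            "m", [Atom(a.element, R @ a.coords + 3.0, a.origin, a.serial) for a in cs.atoms]
        )
        F2, N2 = prepare_graph(moved)
        y1, _ = forward(state, F1, N1)
        y2, _ = forward(state, F2, N2)
        assert abs(y1 - y2) < 1e-8

    def test_permutation_invariance(self, rng):
        from conftest import random_complex

        cs = random_complex(rng, n_ligand=4, n_protein=12)
        perm = rng.permutation(len(cs.atoms))
        permuted = ComplexStructure("p", [cs.atoms[i] for i in perm])
        state = tiny_state(m=18)
        y1, _ = forward(state, *prepare_graph(cs))
        y2, _ = forward(state, *prepare_graph(permuted))
        assert abs(y1 - y2) < 1e-8

    def test_slice_count_mismatch(self, rng):
        site = random_site(rng, 3, 5)
        N = normalize(build_adjacency_tensor(site, "AGIMA_SAM"))
        state = tiny_state(m=18)  # expects K=2
        with pytest.raises(ValueError, match="slices"):
            forward(state, np.zeros((site.n, 18)), N)


class TestGradients:
    def test_analytic_matches_numerical(self, rng):
        """Backprop gradients agree with central differences to 1e-5."""
        site = random_site(rng, 3, 4)
        N = normalize(build_adjacency_tensor(site, "AGIMA_2"))
        F = rng.normal(size=(site.n, 5))
        cfg = ModelConfig(feature_set="F18", conv_dim=3, dense_dims=(4,),
                          dropout_rate=0.0, activation="tanh", seed=2)
        state = init_state(cfg, 18, np.random.default_rng(2))
        # shrink to a 5-wide feature space for speed
        state.W_conv = [rng.normal(size=(5, 3)) * 0.3 for _ in range(2)]
        label = 1.3

        def loss():
            y, _, _ = _forward_pass(state, F, N.slices, False, None)
            return (y - label) ** 2

        y, _, cache = _forward_pass(state, F, N.slices, False, None)
        grads = _backward_pass(state, cache, 2.0 * (y - label))
        analytic = (list(grads["W_conv"]) + list(grads["W_dense"])
                    + list(grads["b_dense"]) + [grads["w_out"], grads["b_out"]])
        params = state.parameters()
        eps = 1e-6
        for p, g in zip(params, analytic):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-5, f"param shape {p.shape} idx {idx}"


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_task(self):
        ds = make_labeled_dataset(
            SyntheticTaskSpec(n_complexes=60, weight_range1=1.0, weight_range2=0.0,
                              noise_sd=0.0, seed=77, max_contacts_per_range=5)
        )
        return prepare_dataset(ds)

    def test_realizable_target_loss_small(self, tiny_task):
        cfg = ModelConfig(conv_dim=16, dense_dims=(32,), dropout_rate=0.0,
                          epochs=120, batch_size=16, learning_rate=3e-3, seed=5)
        state = train(tiny_task, None, cfg)
        preds = [forward(state, F, N)[0] for F, N, _ in tiny_task]
        labels = [l for _, _, l in tiny_task]
        assert np.sqrt(np.mean((np.array(preds) - np.array(labels)) ** 2)) < 0.25

    def test_determinism(self, tiny_task):
        cfg = ModelConfig(conv_dim=8, dense_dims=(8,), epochs=5, seed=9)
        s1 = train(tiny_task[:20], None, cfg)
        s2 = train(tiny_task[:20], None, cfg)
        for p1, p2 in zip(s1.parameters(), s2.parameters()):
            assert np.array_equal(p1, p2)

    def test_empty_dataset(self):
        with pytest.raises(ValueError, match="empty"):
            train([], None, ModelConfig())

    def test_predict_batch(self, tiny_task):
        cfg = ModelConfig(conv_dim=8, dense_dims=(8,), epochs=3, seed=9)
        state = train(tiny_task[:20], None, cfg)
        assert predict_batch(state, []) == []
        items = [(f"c{i}", F, N) for i, (F, N, _) in enumerate(tiny_task[:5])]
        batch = predict_batch(state, items)
        singles = [predict_batch(state, [it])[0].score for it in items]
        assert [p.score for p in batch] == singles
        dup = predict_batch(state, [items[0], items[0]])
        assert dup[0].score == dup[1].score

    def test_checkpoint_roundtrip(self, tiny_task, tmp_path):
        cfg = ModelConfig(conv_dim=8, dense_dims=(8,), epochs=3, seed=9)
        state = train(tiny_task[:20], None, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        F, N, _ = tiny_task[0]
        assert forward(loaded, F, N)[0] == forward(state, F, N)[0]
        assert loaded.config == state.config
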