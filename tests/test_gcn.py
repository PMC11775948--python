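import numpy as np
import pytest

import pathgcn as pg
from pathgcn.fingerprints import N_GLOBAL
from pathgcn.gcn import _sigmoid, _softmax, predict_smiles

from conftest import random_molecular_graph


def straight_line_embedding_oracle(X0, A, weights):
    """Independent step-by-step evaluation of the propagation equations.

    Normalizes the adjacency from first principles (explicit degree matrix,
    explicit matrix products, per-entry ReLU loop) and averages the final
    node embeddings — deliberately naive, shared with nothing in the
    package.
    """
    n = A.shape[0]
    A_hat = A.astype(float) + np.eye(n)
    D_hat = np.diag(A_hat.sum(axis=1))
    D_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(D_hat)))
    A_norm = D_inv_sqrt.dot(A_hat).dot(D_inv_sqrt)
    X = X0.astype(float).copy()
    for W in weights:
        Z = A_norm.dot(X).dot(W)
        for i in range(Z.shape[0]):
            for j in range(Z.shape[1]):
                Z[i, j] = Z[i, j] if Z[i, j] > 0 else 0.0
        X = Z
    v = np.zeros(X.shape[1])
    for i in range(n):
        v += X[i]
    return v / n


class TestNormalizeAdjacency:
    def test_single_node(self):
        assert np.array_equal(pg.normalize_adjacency(np.zeros((1, 1))), [[1.0]])

    def test_two_nodes_single_bond(self):
        out = pg.normalize_adjacency(np.array([[0, 1], [1, 0]]))
        assert np.allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_path_of_three(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        out = pg.normalize_adjacency(A)
        assert np.allclose(np.diag(out), [0.5, 1 / 3, 0.5])
        assert out[0, 1] == pytest.approx(1 / np.sqrt(6))
        assert out[1, 2] == pytest.approx(1 / np.sqrt(6))
        assert out[0, 2] == 0.0

    def test_symmetry_and_weighted_degrees(self):
        A = np.array([[0, 2, 0], [2, 0, 3], [0, 3, 0]])
        out = pg.normalize_adjacency(A)
        assert np.allclose(out, out.T)
        # weighted row sums: D_hat = diag(3, 6, 4)
        assert out[0, 0] == pytest.approx(1 / 3)
        assert out[0, 1] == pytest.approx(2 / np.sqrt(18))

    def test_binarize_mode(self):
        A = np.array([[0, 3], [3, 0]])
        out = pg.normalize_adjacency(A, binarize=True)
        assert np.allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_eigenvalues_within_unit_interval(self, rng):
        for _ in range(50):
            g = random_molecular_graph(rng)
            eig = np.linalg.eigvalsh(pg.normalize_adjacency(g.adjacency))
            assert np.all(eig >= -1 - 1e-9) and np.all(eig <= 1 + 1e-9)


class TestForwardEmbedding:
    def test_single_node_identity_weights(self, rng):
        X0 = rng.standard_normal((1, 6))
        A_norm = pg.normalize_adjacency(np.zeros((1, 1)))
        out = pg.forward_embedding(X0, A_norm, [np.eye(6)] * 3)
        assert np.allclose(out, np.maximum(X0[0], 0.0))

    def test_zero_first_layer_gives_zero(self, rng):
        g = random_molecular_graph(rng)
        X0 = rng.standard_normal((g.n_atoms, 4))
        A_norm = pg.normalize_adjacency(g.adjacency)
        weights = [np.zeros((4, 4)), rng.standard_normal((4, 4))]
        assert np.allclose(pg.forward_embedding(X0, A_norm, weights), 0.0)

    def test_matches_straight_line_oracle(self, rng):
        for _ in range(100):
            g = random_molecular_graph(rng, max_nodes=8)
            d = int(rng.integers(1, 6))
            n_layers = int(rng.integers(1, 4))
            X0 = rng.standard_normal((g.n_atoms, d))
            weights = [rng.standard_normal((d, d)) for _ in range(n_layers)]
            ours = pg.forward_embedding(
                X0, pg.normalize_adjacency(g.adjacency), weights
            )
            oracle = straight_line_embedding_oracle(X0, g.adjacency, weights)
            assert np.allclose(ours, oracle, atol=1e-6)

    def test_nonfinite_error_names_layer(self, rng):
        X0 = np.full((2, 3), 1e308)
        A_norm = pg.normalize_adjacency(np.array([[0, 1], [1, 0]]))
        weights = [np.full((3, 3), 1e308)]
        with pytest.raises(FloatingPointError, match="layer 0"):
            pg.forward_embedding(X0, A_norm, weights)

    def test_permutation_invariance_of_graph_embedding(self, rng):
        vocab = pg.SubgraphVocabulary(radius=2, dim=10, master_seed=1)
        weights = [rng.standard_normal((10, 10)) for _ in range(3)]
        for _ in range(30):
            g = random_molecular_graph(rng)
            perm = rng.permutation(g.n_atoms)
            permuted = pg.MolecularGraph(
                atom_labels=tuple(g.atom_labels[i] for i in perm),
                adjacency=g.adjacency[np.ix_(perm, perm)],
            )
            def embed(graph):
                ids = pg.subgraph_ids(graph, 2)
                X0 = pg.init_node_embeddings(ids, vocab)
                return pg.forward_embedding(
                    X0, pg.normalize_adjacency(graph.adjacency), weights
                )
            a, b = embed(g), embed(permuted)
            assert np.allclose(a, b, rtol=1e-6, atol=1e-9)


class TestHeads:
    def _zero_head_model(self, head, use_global=False):
        hp = pg.GCNHyperparams(
            dim=4, layers=1, radius=0, head=head,
            use_global_features=use_global, seed=0,
        )
        p = hp.head_input_dim
        return pg.TrainedModel(
            gcn_weights=[np.eye(4)],
            head_weights={
                "W1": np.zeros((4, p)), "b1": np.zeros(4),
                "W2": np.zeros((11, 4)), "b2": np.zeros(11),
            },
            vocab=pg.SubgraphVocabulary(radius=0, dim=4, master_seed=0),
            hyperparams=hp,
        )

    def test_zero_weights_softmax_uniform(self):
        model = self._zero_head_model("softmax")
        probs = pg.predict(model, pg.parse_smiles("CCO"))
        assert np.allclose(probs, 1 / 11)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_weights_sigmoid_half(self):
        model = self._zero_head_model("sigmoid")
        probs = pg.predict(model, pg.parse_smiles("CCO"))
        assert np.allclose(probs, 0.5)

    def test_missing_global_features_rejected(self):
        model = self._zero_head_model("softmax", use_global=True)
        with pytest.raises(ValueError, match="global features"):
            pg.predict(model, pg.parse_smiles("CCO"), w=None)

    def test_softmax_normalization_random_weights(self, rng):
        # probability-simplex invariants over many random weight settings
        for _ in range(1000):
            z = rng.standard_normal(11) * rng.uniform(0.1, 50)
            p = _softmax(z)
            assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-9)
            # strict openness checked where float rounding cannot saturate
            s = _sigmoid(np.clip(z, -10, 10))
            assert np.all((s > 0) & (s < 1))


class TestDecideMultilabel:
    def test_threshold_application(self):
        probs = np.array([0.9] + [0.1] * 10)
        assert "".join(map(str, pg.decide_multilabel(probs))) == "10000000000"

    def test_boundary_is_inclusive(self):
        assert np.all(pg.decide_multilabel(np.full(11, 0.5)) == 1)
        assert np.all(pg.decide_multilabel(np.full(11, 0.49)) == 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pg.decide_multilabel(np.full(11, 1.5))


class TestTraining:
    def test_separable_two_class_fit(self, small_single_dataset, tiny_model):
        probs = np.vstack(
            [predict_smiles(tiny_model, s) for s in small_single_dataset.smiles]
        )
        acc = pg.topn_accuracy(probs, small_single_dataset.labels, 1)
        assert acc >= 90.0

    def test_loss_decreases_on_separable_data(self, tiny_model):
        log = tiny_model.training_log
        assert log[-1]["train_loss"] <= log[0]["train_loss"]

    def test_bitwise_determinism(self, small_single_dataset, tiny_hyperparams):
        a = pg.train(small_single_dataset, tiny_hyperparams)
        b = pg.train(small_single_dataset, tiny_hyperparams)
        for Wa, Wb in zip(a.gcn_weights, b.gcn_weights):
            assert np.array_equal(Wa, Wb)
        for k in a.head_weights:
            assert np.array_equal(a.head_weights[k], b.head_weights[k])

    def test_sigmoid_loss_is_nonnegative_bce_sum(self, small_multi_dataset):
        hp = pg.GCNHyperparams(
            dim=8, layers=1, radius=1, epochs=3, head="sigmoid", seed=2
        )
        model = pg.train(small_multi_dataset, hp)
        assert all(e["train_loss"] >= 0 for e in model.training_log)

    def test_head_label_mode_mismatch_rejected(self, small_multi_dataset,
                                               small_single_dataset):
        with pytest.raises(ValueError, match="single-class"):
            pg.train(small_multi_dataset, pg.GCNHyperparams(head="softmax"))
        with pytest.raises(ValueError, match="multi-label"):
            pg.train(small_single_dataset, pg.GCNHyperparams(head="sigmoid"))

    def test_empty_dataset_rejected(self):
        ds = pg.LabeledDataset(records=[], label_mode="single")
        with pytest.raises(ValueError, match="empty"):
            pg.train(ds, pg.GCNHyperparams(epochs=1))

    def test_validation_checkpoint_recorded(self, small_single_dataset):
        hp = pg.GCNHyperparams(dim=8, layers=1, radius=1, epochs=4, seed=3)
        (tr, va, _), = pg.stratified_splits(
            small_single_dataset, (0.8, 0.1, 0.1), 1, seed=3
        )
        model = pg.train(
            small_single_dataset.subset(tr), hp,
            validation=small_single_dataset.subset(va),
        )
        assert all("val_loss" in e for e in model.training_log)


class TestModelContract:
    def test_parameter_count_closed_form(self, tiny_model):
        hp = tiny_model.hyperparams
        d, p = hp.dim, hp.head_input_dim
        expected = hp.layers * d * d + (d * p + d) + (11 * d + 11)
        assert tiny_model.parameter_count() == expected

    def test_default_gcn_weight_count_is_7500(self):
        hp = pg.GCNHyperparams()  # d=50, l=3
        assert hp.layers * hp.dim**2 == 7500

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        back = pg.TrainedModel.load(path)
        for Wa, Wb in zip(tiny_model.gcn_weights, back.gcn_weights):
            assert np.array_equal(Wa, Wb)
        assert back.class_space.names == tiny_model.class_space.names
        probs_a = predict_smiles(tiny_model, "CC(=O)O")
        probs_b = predict_smiles(back, "CC(=O)O")
        assert np.allclose(probs_a, probs_b)

    def test_format_version_mismatch_rejected(self, tiny_model, tmp_path):
        import json

        path = tmp_path / "model.npz"
        tiny_model.save(path)
        with np.load(path) as archive:
            arrays = {k: archive[k] for k in archive.files}
        meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode())
        meta["format_version"] = 999
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="format version"):
            pg.TrainedModel.load(path)


class TestExtractEmbeddings:
    def test_single_atom_molecule(self, tiny_model):
        ds = pg.LabeledDataset(records=[("a", "C", 0)], label_mode="single")
        emb = pg.extract_embeddings(tiny_model, ds)
        assert emb.shape == (1, tiny_model.hyperparams.dim)

    def test_duplicate_molecules_identical_rows(self, tiny_model):
        ds = pg.LabeledDataset(
            records=[("a", "CCO", 0), ("b", "CCO", 0)], label_mode="single"
        )
        emb = pg.extract_embeddings(tiny_model, ds)
        assert np.array_equal(emb[0], emb[1])

    def test_benzene_equals_single_node_embedding(self, tiny_model):
        # all six nodes share X(0) and the graph is vertex-transitive, so
        # pooling changes nothing
        g = pg.parse_smiles("c1ccccc1")
        hp = tiny_model.hyperparams
        ids = pg.subgraph_ids(g, hp.radius)
        X0 = pg.init_node_embeddings(ids, tiny_model.vocab)
        A_norm = pg.normalize_adjacency(g.adjacency)
        v_G = pg.forward_embedding(X0, A_norm, tiny_model.gcn_weights)
        X = X0
        for W in tiny_model.gcn_weights:
            X = np.maximum(A_norm @ X @ W, 0.0)
        assert np.allclose(v_G, X[0], atol=1e-9)
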