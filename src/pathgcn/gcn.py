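"""Graph convolutional network for molecular pathway-class prediction.

The model propagates initial r-radius-subgraph node embeddings X(0) through
l layers of

    X(t+1) = ReLU( A_hat_norm  X(t)  W(t) ),

where A_hat_norm = D^{-1/2} (A + I) D^{-1/2} is the symmetric-normalized,
self-looped, bond-multiplicity-weighted adjacency.  The final node
embeddings are mean-pooled into a graph embedding v_G, optionally
concatenated with the 173-dim global molecular feature vector w, and passed
through a fully connected feed-forward head (one hidden layer of width d,
ReLU) to 11 class outputs — SoftMax for single-class prediction, or
element-wise sigmoid for mixed-membership multi-label prediction.

Training minimizes cross-entropy (softmax head) or the sum of 11 binary
cross-entropies (sigmoid head) with Adam, one molecule per step, iterating
the training set in seeded shuffled order.  The implementation is plain
numpy with hand-derived gradients: the parameter count is small (a few
thousand weights) and molecules are small graphs, so dense matrix
arithmetic is all that is needed, and runs are bitwise reproducible from
the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import (
    CLASS_NAMES,
    ClassLabelSpace,
    LabeledDataset,
    MolecularGraph,
    N_CLASSES,
    parse_smiles,
)
from .fingerprints import (
    N_GLOBAL,
    GlobalFeatureVector,
    SubgraphVocabulary,
    global_features,
    init_node_embeddings,
    subgraph_ids,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GCNHyperparams:
    """Hyperparameters of the GCN and its training loop."""

    dim: int = 50
    layers: int = 3
    radius: int = 2
    learning_rate: float = 1e-3
    epochs: int = 100
    head: str = "softmax"
    use_global_features: bool = False
    binarize_adjacency: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.layers < 1:
            raise ValueError(f"layers must be >= 1, got {self.layers}")
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.head not in ("softmax", "sigmoid"):
            raise ValueError(f"head must be 'softmax' or 'sigmoid', got {self.head!r}")

    @property
    def head_input_dim(self) -> int:
        return self.dim + (N_GLOBAL if self.use_global_features else 0)


def normalize_adjacency(A: np.ndarray, binarize: bool = False) -> np.ndarray:
    """Symmetric normalization with self-loops.

    A_hat = A + I; D_hat = diag(row sums of A_hat);
    returns D_hat^{-1/2} A_hat D_hat^{-1/2}.

    ``binarize`` collapses bond multiplicities to 0/1 before normalizing.
    Self-loops make every degree strictly positive, so no epsilon guard is
    needed, including for single-atom or disconnected graphs.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if binarize:
        A = (A > 0).astype(float)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def forward_embedding(
    X0: np.ndarray, A_norm: np.ndarray, weights: list[np.ndarray]
) -> np.ndarray:
    """Graph embedding v_G: l propagation layers, then mean pooling."""
    X = X0
    for t, W in enumerate(weights):
        X = np.maximum(A_norm @ X @ W, 0.0)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError(f"non-finite values after GCN layer {t}")
    return X.mean(axis=0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class TrainedModel:
    """A trained GCN: propagation weights, head weights and fitted context.

    ``head_weights`` holds W1 (d×p), b1 (d), W2 (11×d), b2 (11) where
    p = d (+173 with global features).  The class order and the subgraph
    vocabulary travel with the model so inference can never permute labels
    or re-randomize initial embeddings.
    """

    gcn_weights: list[np.ndarray]
    head_weights: dict[str, np.ndarray]
    vocab: SubgraphVocabulary
    hyperparams: GCNHyperparams
    class_space: ClassLabelSpace = field(default_factory=ClassLabelSpace)
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        hp = self.hyperparams
        if len(self.gcn_weights) != hp.layers:
            raise ValueError(
                f"expected {hp.layers} GCN weight matrices, got {len(self.gcn_weights)}"
            )
        for W in self.gcn_weights:
            if W.shape != (hp.dim, hp.dim):
                raise ValueError(f"GCN weight shape {W.shape} != ({hp.dim}, {hp.dim})")
        if self.head_weights["W1"].shape != (hp.dim, hp.head_input_dim):
            raise ValueError("head input width mismatch")

    def parameter_count(self) -> int:
        """Total trainable weights: l·d² plus the feed-forward head."""
        hp = self.hyperparams
        p = hp.head_input_dim
        return hp.layers * hp.dim**2 + (hp.dim * p + hp.dim) + (
            N_CLASSES * hp.dim + N_CLASSES
        )

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a single .npz archive (weights + metadata)."""
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "hyperparams": {
                "dim": self.hyperparams.dim,
                "layers": self.hyperparams.layers,
                "radius": self.hyperparams.radius,
                "learning_rate": self.hyperparams.learning_rate,
                "epochs": self.hyperparams.epochs,
                "head": self.hyperparams.head,
                "use_global_features": self.hyperparams.use_global_features,
                "binarize_adjacency": self.hyperparams.binarize_adjacency,
                "seed": self.hyperparams.seed,
            },
            "class_names": list(self.class_space.names),
            "vocab": self.vocab.to_jsonable(),
            "training_log": self.training_log,
        }
        arrays = {f"gcn_W{t}": W for t, W in enumerate(self.gcn_weights)}
        arrays.update({f"head_{k}": v for k, v in self.head_weights.items()})
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta_json"].tobytes()).decode())
            if meta.get("format_version") != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model format version {meta.get('format_version')} is not "
                    f"supported (expected {MODEL_FORMAT_VERSION})"
                )
            hp = GCNHyperparams(**meta["hyperparams"])
            gcn_weights = [archive[f"gcn_W{t}"] for t in range(hp.layers)]
            head_weights = {
                k.removeprefix("head_"): archive[k]
                for k in archive.files
                if k.startswith("head_")
            }
        return cls(
            gcn_weights=gcn_weights,
            head_weights=head_weights,
            vocab=SubgraphVocabulary.from_jsonable(meta["vocab"]),
            hyperparams=hp,
            class_space=ClassLabelSpace(names=tuple(meta["class_names"])),
            training_log=meta.get("training_log", []),
        )


def _head_forward(
    model_head: dict[str, np.ndarray], v_emb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feed-forward head: hidden pre-activation, hidden, logits."""
    pre = model_head["W1"] @ v_emb + model_head["b1"]
    h = np.maximum(pre, 0.0)
    z = model_head["W2"] @ h + model_head["b2"]
    return pre, h, z


def predict(
    model: TrainedModel,
    graph: MolecularGraph,
    w: GlobalFeatureVector | np.ndarray | None = None,
) -> np.ndarray:
    """Class probability vector for one molecule.

    SoftMax head: a distribution over the 11 classes (sums to 1).
    Sigmoid head: 11 independent membership probabilities in (0, 1).
    """
    hp = model.hyperparams
    if hp.use_global_features and w is None:
        raise ValueError(
            "model was trained with global features; w must be provided"
        )
    ids = subgraph_ids(graph, hp.radius)
    X0 = init_node_embeddings(ids, model.vocab)
    A_norm = normalize_adjacency(graph.adjacency, binarize=hp.binarize_adjacency)
    v_G = forward_embedding(X0, A_norm, model.gcn_weights)
    if hp.use_global_features:
        w_arr = w.as_array() if isinstance(w, GlobalFeatureVector) else np.asarray(w)
        v_emb = np.concatenate([v_G, w_arr])
    else:
        v_emb = v_G
    _, _, z = _head_forward(model.head_weights, v_emb)
    return _softmax(z) if hp.head == "softmax" else _sigmoid(z)


def predict_smiles(model: TrainedModel, smiles: str) -> np.ndarray:
    """Convenience: parse, featurize as the model requires, and predict."""
    graph = parse_smiles(smiles)
    w = global_features(smiles) if model.hyperparams.use_global_features else None
    return predict(model, graph, w)


def decide_multilabel(probs: np.ndarray) -> np.ndarray:
    """Threshold membership probabilities at one half (inclusive)."""
    probs = np.asarray(probs)
    if probs.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} probabilities, got {probs.shape}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= 0.5).astype(np.int64)


class _Adam:
    """Adam optimizer over a dict of parameter arrays (standard defaults)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _prepare_sample(
    smiles: str, hp: GCNHyperparams, vocab: SubgraphVocabulary
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    graph = parse_smiles(smiles)
    ids = subgraph_ids(graph, hp.radius)
    X0 = init_node_embeddings(ids, vocab)
    A_norm = normalize_adjacency(graph.adjacency, binarize=hp.binarize_adjacency)
    w = global_features(smiles).as_array() if hp.use_global_features else None
    return X0, A_norm, w


def _loss_and_grads(
    params: dict[str, np.ndarray],
    hp: GCNHyperparams,
    X0: np.ndarray,
    A_norm: np.ndarray,
    w: np.ndarray | None,
    target: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """One molecule's loss and gradients, derived by hand.

    For both heads the logit gradient is (probabilities - target): the
    softmax/cross-entropy and sigmoid/binary-cross-entropy pairings share
    that cancellation.
    """
    l, d = hp.layers, hp.dim
    # forward, keeping intermediates
    Xs = [X0]
    AXs = []  # A_norm @ X(t), reused in the backward pass
    for t in range(l):
        AX = A_norm @ Xs[t]
        AXs.append(AX)
        Xs.append(np.maximum(AX @ params[f"G{t}"], 0.0))
    N = X0.shape[0]
    v_G = Xs[l].mean(axis=0)
    v_emb = np.concatenate([v_G, w]) if w is not None else v_G
    pre = params["W1"] @ v_emb + params["b1"]
    h = np.maximum(pre, 0.0)
    z = params["W2"] @ h + params["b2"]

    if hp.head == "softmax":
        p = _softmax(z)
        true_idx = int(np.argmax(target))
        loss = -float(np.log(max(p[true_idx], 1e-300)))
    else:
        p = _sigmoid(z)
        # stable sum of per-class BCE: log(1+e^z) - t*z
        loss = float(np.sum(np.logaddexp(0.0, z) - target * z))
    dz = p - target

    grads: dict[str, np.ndarray] = {}
    grads["W2"] = np.outer(dz, h)
    grads["b2"] = dz
    dh = params["W2"].T @ dz
    dpre = dh * (pre > 0)
    grads["W1"] = np.outer(dpre, v_emb)
    grads["b1"] = dpre
    dv_emb = params["W1"].T @ dpre
    dv_G = dv_emb[:d]
    dX = np.tile(dv_G / N, (N, 1))
    for t in range(l - 1, -1, -1):
        dZ = dX * (Xs[t + 1] > 0)
        grads[f"G{t}"] = AXs[t].T @ dZ
        if t > 0:
            dX = A_norm @ dZ @ params[f"G{t}"].T
    return loss, grads


def _init_params(hp: GCNHyperparams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-style initialization for the ReLU layers; zero biases."""
    params: dict[str, np.ndarray] = {}
    for t in range(hp.layers):
        params[f"G{t}"] = rng.standard_normal((hp.dim, hp.dim)) * np.sqrt(2.0 / hp.dim)
    p = hp.head_input_dim
    params["W1"] = rng.standard_normal((hp.dim, p)) * np.sqrt(2.0 / p)
    params["b1"] = np.zeros(hp.dim)
    params["W2"] = rng.standard_normal((N_CLASSES, hp.dim)) * np.sqrt(2.0 / hp.dim)
    params["b2"] = np.zeros(N_CLASSES)
    return params


def train(
    dataset: LabeledDataset,
    hyperparams: GCNHyperparams | None = None,
    validation: LabeledDataset | None = None,
) -> TrainedModel:
    """Train the GCN on a labeled dataset.

    One Adam step per molecule; each epoch visits the training set in a
    seeded shuffled order.  If a validation set is supplied, the parameters
    from the epoch with the lowest validation loss are the ones returned
    (best-epoch checkpoint); otherwise the final-epoch parameters are.
    Fully deterministic given ``hyperparams.seed``.
    """
    hp = hyperparams or GCNHyperparams()
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    if hp.head == "softmax" and dataset.label_mode != "single":
        raise ValueError("softmax head requires single-class labels")
    if hp.head == "sigmoid" and dataset.label_mode != "multi":
        raise ValueError("sigmoid head requires multi-label membership vectors")

    rng = np.random.default_rng(hp.seed)
    vocab = SubgraphVocabulary(radius=hp.radius, dim=hp.dim, master_seed=hp.seed)
    params = _init_params(hp, rng)
    optimizer = _Adam(params, hp.learning_rate)

    targets = dataset.membership_matrix().astype(float)
    samples = [
        _prepare_sample(smi, hp, vocab) for smi in dataset.smiles
    ]
    val_samples = None
    val_targets = None
    if validation is not None and len(validation) > 0:
        val_samples = [_prepare_sample(smi, hp, vocab) for smi in validation.smiles]
        val_targets = validation.membership_matrix().astype(float)

    training_log: list[dict] = []
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    m = len(samples)
    for epoch in range(hp.epochs):
        order = rng.permutation(m)
        total = 0.0
        for i in order:
            X0, A_norm, w = samples[i]
            loss, grads = _loss_and_grads(params, hp, X0, A_norm, w, targets[i])
            optimizer.step(params, grads)
            total += loss
        entry = {"epoch": epoch + 1, "train_loss": total / m}
        if val_samples is not None:
            val_loss = 0.0
            for j, (X0, A_norm, w) in enumerate(val_samples):
                loss, _ = _loss_and_grads(params, hp, X0, A_norm, w, val_targets[j])
                val_loss += loss
            val_loss /= len(val_samples)
            entry["val_loss"] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
        training_log.append(entry)
    if training_log[-1]["train_loss"] > training_log[0]["train_loss"]:
        logger.warning(
            "final-epoch loss %.4f exceeds first-epoch loss %.4f",
            training_log[-1]["train_loss"],
            training_log[0]["train_loss"],
        )
    if best_params is not None:
        params = best_params

    gcn_weights = [params[f"G{t}"] for t in range(hp.layers)]
    head_weights = {k: params[k] for k in ("W1", "b1", "W2", "b2")}
    return TrainedModel(
        gcn_weights=gcn_weights,
        head_weights=head_weights,
        vocab=vocab,
        hyperparams=hp,
        class_space=dataset.class_space,
        training_log=training_log,
    )


def extract_embeddings(model: TrainedModel, dataset: LabeledDataset) -> np.ndarray:
    """Graph embedding v_G for every molecule in the dataset: (M, d).

    Pure read of the trained propagation layers — the feed-forward head is
    not applied.  These are the shape features the hybrid random forest
    consumes.
    """
    hp = model.hyperparams
    rows = []
    for smi in dataset.smiles:
        graph = parse_smiles(smi)
        ids = subgraph_ids(graph, hp.radius)
        X0 = init_node_embeddings(ids, model.vocab)
        A_norm = normalize_adjacency(graph.adjacency, binarize=hp.binarize_adjacency)
        rows.append(forward_embedding(X0, A_norm, model.gcn_weights))
    return np.vstack(rows)
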