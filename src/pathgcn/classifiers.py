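"""Classifier zoo around the GCN embeddings.

The headline method is a random forest trained on the learned GCN graph
embeddings.  For comparison the same forest is trained on the 173 global
molecular features and on raw "local graph features" (the initial r-radius
subgraph node embeddings concatenated in atom order) — the latter is the
control showing that a forest cannot extract shape information from
unpooled node features.  Multi-label baselines (kNN, bagged logistic
regression, 11 independent per-class forests) operate on the global
features.

Random forests and the baselines are scikit-learn estimators configured to
the study's settings (300 trees, depth 60, Gini); this module adds the
fixed-length vectorization, the 11-class probability contract and seed
plumbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .chem_io import N_CLASSES, MolecularGraph
from .fingerprints import SubgraphVocabulary, init_node_embeddings, subgraph_ids

logger = logging.getLogger(__name__)

SINGLE_CLASS_KINDS = ("rf_embeddings", "rf_global", "rf_local")
MULTI_LABEL_KINDS = ("knn", "ensemble_logreg", "independent_rfs")


@dataclass(frozen=True)
class RFParams:
    """Random-forest settings: 300 Gini trees of depth at most 60."""

    n_trees: int = 300
    max_depth: int = 60
    split_criterion: str = "gini"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")


def local_graph_features(
    graph: MolecularGraph,
    vocab: SubgraphVocabulary,
    max_atoms: int = 60,
) -> np.ndarray:
    """Concatenated initial node embeddings, padded/truncated to max_atoms·d.

    Rows follow the canonical atom order of the parsed graph; molecules
    larger than ``max_atoms`` are truncated (logged).  This fixed-length
    flattening is what lets a random forest consume raw per-node shape
    features — and why it performs poorly: the encoding is not
    permutation-invariant and discards connectivity.
    """
    ids = subgraph_ids(graph, vocab.radius)
    X0 = init_node_embeddings(ids, vocab)
    n, d = X0.shape
    if n > max_atoms:
        logger.warning(
            "molecule with %d atoms truncated to %d for local features", n, max_atoms
        )
        X0 = X0[:max_atoms]
        n = max_atoms
    out = np.zeros(max_atoms * d)
    out[: n * d] = X0.ravel()
    return out


@dataclass
class FittedClassifier:
    """A fitted member of the model zoo with a uniform probability contract.

    Single-class kinds expose ``predict_proba`` returning an (M, 11)
    row-stochastic matrix.  Multi-label kinds expose
    ``predict_membership_proba`` returning (M, 11) independent per-class
    probabilities, thresholded at one half by ``predict_membership``.
    """

    kind: str
    task: str  # "single" | "multi"
    feature_dim: int
    _estimators: list = field(default_factory=list, repr=False)
    _classes_seen: np.ndarray | None = field(default=None, repr=False)
    _dead_classes: list[int] = field(default_factory=list, repr=False)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if self.task != "single":
            raise ValueError(f"{self.kind} is a multi-label classifier")
        est = self._estimators[0]
        raw = est.predict_proba(np.asarray(features))
        # re-embed into the full 11-class simplex (training may not have
        # seen every class)
        out = np.zeros((raw.shape[0], N_CLASSES))
        out[:, est.classes_.astype(int)] = raw
        return out

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1)

    def predict_membership_proba(self, features: np.ndarray) -> np.ndarray:
        if self.task != "multi":
            raise ValueError(f"{self.kind} is a single-class classifier")
        features = np.asarray(features)
        out = np.zeros((features.shape[0], N_CLASSES))
        for c, est in enumerate(self._estimators):
            if est is None:  # class absent from training
                continue
            proba = est.predict_proba(features)
            if proba.shape[1] == 1:
                out[:, c] = float(est.classes_[0])
            else:
                pos = int(np.flatnonzero(est.classes_ == 1)[0])
                out[:, c] = proba[:, pos]
        return out

    def predict_membership(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_membership_proba(features) >= 0.5).astype(np.int64)


def _make_rf(params: RFParams) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        criterion=params.split_criterion,
        random_state=params.seed,
        n_jobs=1,
    )


def fit_single_class(
    kind: str,
    features: np.ndarray,
    labels: np.ndarray,
    params: RFParams | None = None,
) -> FittedClassifier:
    """Fit a single-class (11-way) random forest on the given features.

    ``kind`` records which feature family the matrix came from
    (rf_embeddings / rf_global / rf_local); the estimator is the same
    forest in each case.
    """
    if kind not in SINGLE_CLASS_KINDS:
        raise ValueError(f"unknown single-class kind {kind!r}")
    params = params or RFParams()
    features = np.asarray(features)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if labels.min() < 0 or labels.max() >= N_CLASSES:
        raise ValueError("labels must be class indices in 0..10")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")
    rf = _make_rf(params)
    rf.fit(features, labels)
    return FittedClassifier(
        kind=kind, task="single", feature_dim=features.shape[1], _estimators=[rf]
    )


def fit_multi_label(
    kind: str,
    features: np.ndarray,
    membership: np.ndarray,
    params: RFParams | None = None,
    k_neighbors: int = 5,
    n_base_learners: int = 25,
) -> FittedClassifier:
    """Fit a multi-label baseline: one binary classifier per pathway class.

    kinds: ``independent_rfs`` (11 separate forests), ``knn`` (per-class
    vote fraction among the k nearest neighbors), ``ensemble_logreg``
    (bagged logistic regressions with averaged probabilities).  A class
    with no positive training examples gets its probability fixed to 0
    (warning logged).
    """
    if kind not in MULTI_LABEL_KINDS:
        raise ValueError(f"unknown multi-label kind {kind!r}")
    params = params or RFParams()
    features = np.asarray(features)
    membership = np.asarray(membership)
    if membership.shape != (features.shape[0], N_CLASSES):
        raise ValueError(
            f"membership must be (M, {N_CLASSES}), got {membership.shape}"
        )
    if not np.isin(membership, (0, 1)).all():
        raise ValueError("membership entries must be 0/1")
    estimators: list = []
    dead: list[int] = []
    for c in range(N_CLASSES):
        y = membership[:, c]
        if y.sum() == 0:
            logger.warning(
                "class %d has no positive training examples; probability fixed to 0",
                c,
            )
            estimators.append(None)
            dead.append(c)
            continue
        if kind == "independent_rfs":
            est = _make_rf(RFParams(
                n_trees=params.n_trees,
                max_depth=params.max_depth,
                split_criterion=params.split_criterion,
                seed=params.seed + c,
            ))
        elif kind == "knn":
            est = KNeighborsClassifier(n_neighbors=min(k_neighbors, len(y)))
        else:  # ensemble_logreg
            est = BaggingClassifier(
                estimator=LogisticRegression(max_iter=1000),
                n_estimators=n_base_learners,
                random_state=params.seed + c,
                n_jobs=1,
            )
        est.fit(features, y)
        estimators.append(est)
    return FittedClassifier(
        kind=kind,
        task="multi",
        feature_dim=features.shape[1],
        _estimators=estimators,
        _dead_classes=dead,
    )


def topk_to_membership(probs: np.ndarray, k: int) -> np.ndarray:
    """Declare the top-k classes as members, the rest as non-members.

    Converts a ranking classifier's probability vector into an 11-bit
    membership vector; ties are broken toward the lower class index.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} probabilities, got {probs.shape}")
    if not 1 <= k <= N_CLASSES:
        raise ValueError(f"k must be in 1..{N_CLASSES}, got {k}")
    # stable sort on (-prob, index): equal probabilities keep index order
    order = np.argsort(-probs, kind="stable")
    out = np.zeros(N_CLASSES, dtype=np.int64)
    out[order[:k]] = 1
    return out
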