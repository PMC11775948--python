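"""Benchmark orchestration: the model-zoo comparisons on one dataset.

``run_single_class_benchmark`` reproduces the single-class comparison
table: random forests on GCN embeddings / global molecular features /
local graph features, plus the end-to-end GCN with and without global
features, scored by top-1/2/3 accuracy over repeated 80/10/10 splits, with
exact McNemar tests between model pairs on the final repeat.

``run_multilabel_benchmark`` reproduces the mixed-membership comparison:
the sigmoid-head GCN (+ global features) against kNN, ensemble logistic
regression and 11 independent per-class random forests on global features,
scored by bit-wise accuracy, micro precision/recall, Hamming loss, exact
match, and per-class metrics for the GCN.
"""

from __future__ import annotations

import logging

import numpy as np

from .chem_io import LabeledDataset, parse_smiles, stratified_splits
from .classifiers import (
    RFParams,
    fit_multi_label,
    fit_single_class,
    local_graph_features,
)
from .evaluation import (
    classwise_metrics,
    confusion_from_matrices,
    hamming_exact,
    mcnemar,
    multilabel_accuracy,
    precision_recall,
    topn_accuracy,
)
from .fingerprints import SubgraphVocabulary, global_feature_matrix
from .gcn import GCNHyperparams, extract_embeddings, predict_smiles, train

logger = logging.getLogger(__name__)

SINGLE_CLASS_MODELS = ("rf_embeddings", "rf_global", "rf_local", "gcn", "gcn_global")
MULTI_LABEL_MODELS = ("gcn_global", "knn", "ensemble_logreg", "independent_rfs")


def _local_feature_matrix(
    smiles_list: list[str], vocab: SubgraphVocabulary, max_atoms: int
) -> np.ndarray:
    return np.vstack(
        [
            local_graph_features(parse_smiles(s), vocab, max_atoms=max_atoms)
            for s in smiles_list
        ]
    )


def run_single_class_benchmark(
    dataset: LabeledDataset,
    models: tuple[str, ...] = SINGLE_CLASS_MODELS,
    n_repeats: int = 1,
    seed: int = 0,
    hyperparams: GCNHyperparams | None = None,
    rf_params: RFParams | None = None,
    max_atoms: int = 60,
) -> dict:
    """Top-1/2/3 accuracy table over repeated splits, plus McNemar tests.

    Returns a report dict: per model, mean and standard deviation of top-n
    accuracy over the repeats; ``mcnemar`` maps "a_vs_b" to the exact
    two-sided p-value comparing top-1 correctness on the final repeat's
    test set.
    """
    if dataset.label_mode != "single":
        raise ValueError("single-class benchmark needs a single-class dataset")
    unknown = set(models) - set(SINGLE_CLASS_MODELS)
    if unknown:
        raise ValueError(f"unknown model kind(s): {sorted(unknown)}")
    base_hp = hyperparams or GCNHyperparams()
    rf_params = rf_params or RFParams(seed=seed)

    splits = stratified_splits(dataset, (0.8, 0.1, 0.1), n_repeats=n_repeats, seed=seed)
    accs: dict[str, dict[int, list[float]]] = {
        m: {1: [], 2: [], 3: []} for m in models
    }
    correctness: dict[str, np.ndarray] = {}

    for rep, (tr, va, te) in enumerate(splits):
        train_ds, val_ds, test_ds = (
            dataset.subset(tr),
            dataset.subset(va),
            dataset.subset(te),
        )
        rep_seed = seed + rep
        hp = GCNHyperparams(
            dim=base_hp.dim,
            layers=base_hp.layers,
            radius=base_hp.radius,
            learning_rate=base_hp.learning_rate,
            epochs=base_hp.epochs,
            head="softmax",
            use_global_features=False,
            binarize_adjacency=base_hp.binarize_adjacency,
            seed=rep_seed,
        )
        probs: dict[str, np.ndarray] = {}

        needs_backbone = {"rf_embeddings", "rf_local", "gcn"} & set(models)
        model = train(train_ds, hp, validation=val_ds) if needs_backbone else None

        if "gcn" in models:
            probs["gcn"] = np.vstack(
                [predict_smiles(model, s) for s in test_ds.smiles]
            )
        if "rf_embeddings" in models:
            emb_tr = extract_embeddings(model, train_ds)
            emb_te = extract_embeddings(model, test_ds)
            rf = fit_single_class("rf_embeddings", emb_tr, train_ds.labels, rf_params)
            probs["rf_embeddings"] = rf.predict_proba(emb_te)
        if "rf_local" in models:
            vocab = model.vocab
            loc_tr = _local_feature_matrix(train_ds.smiles, vocab, max_atoms)
            loc_te = _local_feature_matrix(test_ds.smiles, vocab, max_atoms)
            rf = fit_single_class("rf_local", loc_tr, train_ds.labels, rf_params)
            probs["rf_local"] = rf.predict_proba(loc_te)
        if "rf_global" in models or "gcn_global" in models:
            glob_tr = global_feature_matrix(train_ds.smiles)
            glob_te = global_feature_matrix(test_ds.smiles)
        if "rf_global" in models:
            rf = fit_single_class("rf_global", glob_tr, train_ds.labels, rf_params)
            probs["rf_global"] = rf.predict_proba(glob_te)
        if "gcn_global" in models:
            hp_g = GCNHyperparams(
                dim=hp.dim,
                layers=hp.layers,
                radius=hp.radius,
                learning_rate=hp.learning_rate,
                epochs=hp.epochs,
                head="softmax",
                use_global_features=True,
                binarize_adjacency=hp.binarize_adjacency,
                seed=rep_seed,
            )
            model_g = train(train_ds, hp_g, validation=val_ds)
            probs["gcn_global"] = np.vstack(
                [predict_smiles(model_g, s) for s in test_ds.smiles]
            )

        labels = test_ds.labels
        for m in models:
            for n in (1, 2, 3):
                accs[m][n].append(topn_accuracy(probs[m], labels, n))
            top1 = np.argmax(probs[m], axis=1)
            correctness[m] = (top1 == labels).astype(int)

    report: dict = {"schema_version": 1, "n_repeats": n_repeats, "models": {}}
    for m in models:
        report["models"][m] = {
            f"top{n}": {
                "mean": float(np.mean(accs[m][n])),
                "std": float(np.std(accs[m][n])),
            }
            for n in (1, 2, 3)
        }
    pairs = {}
    model_list = list(models)
    for i, a in enumerate(model_list):
        for b in model_list[i + 1 :]:
            pairs[f"{a}_vs_{b}"] = mcnemar(correctness[a], correctness[b])
    report["mcnemar_top1_final_repeat"] = pairs
    return report


def run_multilabel_benchmark(
    dataset: LabeledDataset,
    models: tuple[str, ...] = MULTI_LABEL_MODELS,
    seed: int = 0,
    hyperparams: GCNHyperparams | None = None,
    rf_params: RFParams | None = None,
) -> dict:
    """Mixed-membership comparison on one 80/10/10 split.

    The GCN uses a sigmoid head with global features; the classical
    baselines consume the global molecular features.  All predictions are
    thresholded at one half before scoring.
    """
    if dataset.label_mode != "multi":
        raise ValueError("multi-label benchmark needs a multi-label dataset")
    unknown = set(models) - set(MULTI_LABEL_MODELS)
    if unknown:
        raise ValueError(f"unknown model kind(s): {sorted(unknown)}")
    base_hp = hyperparams or GCNHyperparams()
    rf_params = rf_params or RFParams(seed=seed)

    (tr, va, te), = stratified_splits(dataset, (0.8, 0.1, 0.1), 1, seed=seed)
    train_ds, val_ds, test_ds = (
        dataset.subset(tr),
        dataset.subset(va),
        dataset.subset(te),
    )
    true_matrix = test_ds.membership_matrix()
    preds: dict[str, np.ndarray] = {}

    if "gcn_global" in models:
        hp = GCNHyperparams(
            dim=base_hp.dim,
            layers=base_hp.layers,
            radius=base_hp.radius,
            learning_rate=base_hp.learning_rate,
            epochs=base_hp.epochs,
            head="sigmoid",
            use_global_features=True,
            binarize_adjacency=base_hp.binarize_adjacency,
            seed=seed,
        )
        model = train(train_ds, hp, validation=val_ds)
        probs = np.vstack([predict_smiles(model, s) for s in test_ds.smiles])
        preds["gcn_global"] = (probs >= 0.5).astype(int)

    classical = {"knn", "ensemble_logreg", "independent_rfs"} & set(models)
    if classical:
        glob_tr = global_feature_matrix(train_ds.smiles)
        glob_te = global_feature_matrix(test_ds.smiles)
        membership_tr = train_ds.membership_matrix()
        for kind in sorted(classical):
            clf = fit_multi_label(kind, glob_tr, membership_tr, rf_params)
            preds[kind] = clf.predict_membership(glob_te)

    report: dict = {"schema_version": 1, "models": {}}
    for m in models:
        pred = preds[m]
        counts = confusion_from_matrices(true_matrix, pred)
        precision, recall = precision_recall(counts)
        hamming, exact = hamming_exact(true_matrix, pred)
        entry = {
            "accuracy_percent": multilabel_accuracy(true_matrix, pred),
            "precision": precision,
            "recall": recall,
            "hamming_loss": hamming,
            "exact_match": exact,
        }
        if m == "gcn_global":
            entry["per_class"] = classwise_metrics(true_matrix, pred)
        report["models"][m] = entry
    return report
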