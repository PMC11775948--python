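"""Interpretability probe: predict global molecular features from embeddings.

After training, each of the 173 global molecular features is regressed on
the d-dimensional GCN graph embeddings: ordinary least squares for
continuous-valued features (reported as adjusted R² on the full fit) and
logistic regression for binary-valued features (reported as holdout
classification accuracy).  High scores indicate that the learned shape
embedding implicitly carries the hand-curated physicochemical information.

The probe is a pure read: it never mutates the model or the embeddings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from .fingerprints import GLOBAL_FEATURE_NAMES, N_MACCS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeRecord:
    """Score for one global feature predicted from the embeddings."""

    feature: str
    kind: str  # "continuous" | "binary"
    score: float | None  # adjusted R² or holdout accuracy; None if skipped
    n_used: int
    flag: str = ""  # "", "constant_feature", "single_level", "no_convergence"


def _adjusted_r2(r2: float, m: int, d: int) -> float:
    return 1.0 - (1.0 - r2) * (m - 1) / (m - d - 1)


def probe(
    embeddings: np.ndarray,
    globals_matrix: np.ndarray,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> list[ProbeRecord]:
    """Fit one regression per global feature on the embedding vectors.

    The first 166 columns of ``globals_matrix`` (MACCS bits) are treated as
    binary, the remaining descriptors as continuous.  Binary probes are
    scored on a seeded holdout split of ``holdout_fraction``; a
    non-convergent logistic fit falls back to majority-class accuracy
    (flagged).  Constant continuous features and single-level binary
    features are skipped with a flag.
    """
    X = np.asarray(embeddings, dtype=float)
    G = np.asarray(globals_matrix, dtype=float)
    if X.ndim != 2 or G.ndim != 2 or X.shape[0] != G.shape[0]:
        raise ValueError("embeddings and globals must be aligned 2-D matrices")
    m, d = X.shape
    if not 0 < holdout_fraction <= 0.5:
        raise ValueError(f"holdout_fraction must be in (0, 0.5], got {holdout_fraction}")
    if m <= d + 2:
        raise ValueError(
            f"need more than d + 2 = {d + 2} samples for the continuous fits, got {m}"
        )
    names = feature_names or GLOBAL_FEATURE_NAMES[: G.shape[1]]
    if len(names) != G.shape[1]:
        raise ValueError("feature_names length must match globals columns")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_hold = max(1, int(round(holdout_fraction * m)))
    hold, fit_idx = perm[:n_hold], perm[n_hold:]

    records: list[ProbeRecord] = []
    for j, name in enumerate(names):
        y = G[:, j]
        is_binary = j < N_MACCS if feature_names is None else set(
            np.unique(y)
        ) <= {0.0, 1.0}
        if is_binary:
            levels = np.unique(y[fit_idx])
            if len(levels) < 2:
                records.append(
                    ProbeRecord(name, "binary", None, m, flag="single_level")
                )
                continue
            clf = LogisticRegression(max_iter=1000, random_state=seed)
            flag = ""
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                clf.fit(X[fit_idx], y[fit_idx])
                if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                    flag = "no_convergence"
            if flag == "no_convergence":
                majority = float(np.bincount(y[fit_idx].astype(int)).argmax())
                score = float(np.mean(y[hold] == majority))
            else:
                score = float(clf.score(X[hold], y[hold]))
            records.append(ProbeRecord(name, "binary", score, m, flag=flag))
        else:
            if np.ptp(y) == 0:
                records.append(
                    ProbeRecord(name, "continuous", None, m, flag="constant_feature")
                )
                continue
            reg = LinearRegression().fit(X, y)
            score = _adjusted_r2(float(reg.score(X, y)), m, d)
            records.append(ProbeRecord(name, "continuous", score, m))
    return records


def probe_report_rows(records: list[ProbeRecord]) -> list[dict]:
    """Ranked JSON-ready rows (highest score first, skipped probes last)."""
    scored = sorted(
        (r for r in records if r.score is not None),
        key=lambda r: -r.score,
    )
    skipped = [r for r in records if r.score is None]
    return [
        {
            "feature": r.feature,
            "kind": r.kind,
            "score": r.score,
            "n_used": r.n_used,
            "flag": r.flag,
        }
        for r in scored + skipped
    ]
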