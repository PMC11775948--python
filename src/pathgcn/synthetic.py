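"""Synthetic planted-motif molecule datasets.

Every pipeline stage is testable without downloading a compound database:
the generator emits valid SMILES whose class membership is determined by
planted substructure motifs.  A molecule is a random alkyl/ether scaffold
chain with the characteristic functional-group motif of each of its
assigned classes attached as a branch.  The motifs are chemically simple
(carboxyl, phosphate, pyridine, nitro, ...) so that both MACCS keys and
r-radius subgraph identifiers can detect them — both feature families
carry class signal, as in the real pathway-class task.

The default condition mirrors the statistical shape of the curated KEGG
compound set: 11 classes, skewed class sizes (largest about five times the
smallest), and roughly 8% of compounds belonging to more than one class
(matching 4935 compounds of which 4539 are single-class).  No attempt is
made to match real KEGG chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import (
    N_CLASSES,
    LabeledDataset,
    SmilesParseError,
    parse_smiles,
)

#: Branch-attachable SMILES fragments, one characteristic motif per class.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "C(=O)O",          # carboxylic acid
    "OP(=O)(O)O",      # phosphate ester
    "C(=O)N",          # amide
    "C#N",             # nitrile
    "S",               # thiol
    "c1ccncc1",        # pyridine
    "c1ccc(O)cc1",     # phenol
    "c1ccoc1",         # furan
    "S(=O)(=O)O",      # sulfonic acid
    "C(F)(F)F",        # trifluoromethyl
    "[N+](=O)[O-]",    # nitro
)


@dataclass
class SyntheticSpec:
    """Specification of a planted-motif dataset.

    Class sizes follow ``class_weights`` (uniform if omitted); a
    ``multi_label_fraction`` of compounds carries the motifs of two or
    three classes.  ``label_noise_rate`` optionally corrupts labels after
    construction, to create non-separable regimes for metric testing.
    """

    n_molecules: int = 500
    n_classes: int = 4
    multi_label_fraction: float = 0.08
    motif_library: tuple[str, ...] = DEFAULT_MOTIFS
    scaffold_size_range: tuple[int, int] = (4, 12)
    label_noise_rate: float = 0.0
    class_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= N_CLASSES:
            raise ValueError(f"n_classes must be in 1..{N_CLASSES}")
        if len(self.motif_library) < self.n_classes:
            raise ValueError("need at least one motif per class")
        for frac in (self.multi_label_fraction, self.label_noise_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.class_weights is not None and len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights length must equal n_classes")

    def weights(self) -> np.ndarray:
        if self.class_weights is None:
            w = np.ones(self.n_classes)
        else:
            w = np.asarray(self.class_weights, dtype=float)
        return w / w.sum()


def kegg_like_spec(n_molecules: int = 1200, seed: int = 0) -> SyntheticSpec:
    """Spec emulating the curated pathway-compound set's statistical shape.

    11 classes with linearly skewed sizes (largest ≈ 5× smallest), ~8%
    mixed-membership compounds, distinct heteroatom-bearing motifs per
    class, and scaffold sizes giving metabolite-scale molecules (roughly
    15–50 heavy atoms, mean ≈ 30).
    """
    return SyntheticSpec(
        n_molecules=n_molecules,
        n_classes=N_CLASSES,
        multi_label_fraction=0.08,
        scaffold_size_range=(12, 45),
        class_weights=tuple(np.linspace(5.0, 1.0, N_CLASSES)),
        seed=seed,
    )


_MAX_RETRIES = 25


def _build_smiles(
    rng: np.random.Generator,
    motifs: list[str],
    size_range: tuple[int, int],
) -> str:
    """Assemble a scaffold chain with the given motifs attached as branches."""
    lo, hi = size_range
    length = int(rng.integers(max(lo, len(motifs) + 1), hi + 1))
    # attachment sites must be carbons; pick distinct chain positions
    sites = sorted(rng.choice(length, size=len(motifs), replace=False).tolist())
    tokens = []
    prev_o = True  # disallow leading/adjacent ether oxygens
    for pos in range(length):
        if pos in sites:
            motif = motifs[sites.index(pos)]
            tokens.append(f"C({motif})")
            prev_o = False
        elif not prev_o and pos != length - 1 and rng.random() < 0.2:
            tokens.append("O")
            prev_o = True
        else:
            tokens.append("C")
            prev_o = False
    return "".join(tokens)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labeled planted-motif dataset.

    Labels reflect the planted motifs exactly (before optional label
    noise).  The returned dataset is in multi-label mode when
    ``multi_label_fraction > 0``, otherwise single-class mode.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    # separate stream: toggling label noise never changes the structures
    noise_rng = np.random.default_rng([spec.seed, 1])
    weights = spec.weights()
    multi_mode = spec.multi_label_fraction > 0
    records: list[tuple[str, str, object]] = []
    for i in range(spec.n_molecules):
        if multi_mode and rng.random() < spec.multi_label_fraction:
            n_members = 2 if rng.random() < 0.8 else 3
            classes = rng.choice(
                spec.n_classes, size=n_members, replace=False, p=weights
            )
        else:
            classes = np.array([rng.choice(spec.n_classes, p=weights)])
        classes = np.sort(classes)
        motifs = [spec.motif_library[c] for c in classes]
        smiles = None
        for _ in range(_MAX_RETRIES):
            candidate = _build_smiles(rng, motifs, spec.scaffold_size_range)
            try:
                parse_smiles(candidate)
            except SmilesParseError:
                continue
            smiles = candidate
            break
        if smiles is None:
            raise RuntimeError(
                f"could not assemble a valid molecule for classes {classes.tolist()} "
                f"after {_MAX_RETRIES} attempts"
            )
        if multi_mode:
            label = np.zeros(N_CLASSES, dtype=np.int64)
            label[classes] = 1
            if spec.label_noise_rate and noise_rng.random() < spec.label_noise_rate:
                flip = int(noise_rng.integers(N_CLASSES))
                label[flip] = 1 - label[flip]
            records.append((f"SYN{i:05d}", smiles, label))
        else:
            label_idx = int(classes[0])
            if spec.label_noise_rate and noise_rng.random() < spec.label_noise_rate:
                label_idx = int(noise_rng.choice(spec.n_classes))
            records.append((f"SYN{i:05d}", smiles, label_idx))
    return LabeledDataset(
        records=records, label_mode="multi" if multi_mode else "single"
    )


def single_class_view(dataset: LabeledDataset) -> LabeledDataset:
    """Single-class subset of a multi-label dataset.

    Keeps compounds with exactly one membership bit and converts their
    labels to class indices — the analogue of restricting a mixed
    compound set to its single-pathway members for the 11-way task.
    """
    if dataset.label_mode == "single":
        return dataset
    records = []
    for cid, smi, bits in dataset.records:
        if int(np.sum(bits)) == 1:
            records.append((cid, smi, int(np.argmax(bits))))
    return LabeledDataset(records=records, label_mode="single",
                          class_space=dataset.class_space)
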