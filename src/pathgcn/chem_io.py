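"""SMILES parsing and labeled-dataset I/O.

Molecules are represented as atom-labeled undirected graphs whose edges are
weighted by bond multiplicity.  Aromatic systems are kekulized so that every
bond carries an integer multiplicity in {1, 2, 3}: the graph convolution
needs a single numeric adjacency, and alternating single/double bonds are
the standard integer-valued reading of an aromatic ring.  Hydrogens are
implicit (heavy-atom graph).

Pathway-class labels live in a fixed, serialized order of the 11 top-level
KEGG metabolic pathway classes; an 11-character 0/1 "association bit-string"
encodes mixed membership (bit i = membership in class i).
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# rdkit is chatty on stderr about kekulization and sanitization; parse
# failures are reported through our own error path instead.
RDLogger.DisableLog("rdApp.*")

#: Canonical order of the 11 top-level KEGG metabolic pathway classes.
#: Immutable; stored with every trained model so a model can never be
#: evaluated against a permuted label order.
CLASS_NAMES: tuple[str, ...] = (
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
    "Metabolism of other amino acids",
    "Glycan biosynthesis and metabolism",
    "Metabolism of cofactors and vitamins",
    "Metabolism of terpenoids and polyketides",
    "Biosynthesis of other secondary metabolites",
    "Xenobiotics biodegradation and metabolism",
)

N_CLASSES = len(CLASS_NAMES)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


@dataclass(frozen=True)
class ClassLabelSpace:
    """Ordered list of pathway-class names; the label space of every model."""

    names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != N_CLASSES:
            raise ValueError(
                f"class label space must have exactly {N_CLASSES} names, "
                f"got {len(self.names)}"
            )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom molecular graph with bond-multiplicity-weighted edges.

    Attributes
    ----------
    atom_labels
        Element symbol per node, length ``n_atoms``.
    adjacency
        Symmetric ``(n_atoms, n_atoms)`` integer matrix; entry (i, j) is the
        multiplicity of the bond between atoms i and j (0 = no bond), after
        kekulization.  Zero diagonal.
    """

    atom_labels: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = self.adjacency
        n = len(self.atom_labels)
        if n < 1:
            raise ValueError("molecular graph needs at least one atom")
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if np.any(A != A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)


# integer bond multiplicities after kekulization
_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a kekulized heavy-atom molecular graph.

    Disconnected SMILES (e.g. salts written with '.') keep all components in
    one graph; the self-loop added during adjacency normalization keeps every
    degree strictly positive, so downstream propagation stays well defined.

    Raises
    ------
    SmilesParseError
        If the string is empty, syntactically invalid, or cannot be
        kekulized.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rdkit-internal
        raise SmilesParseError(f"cannot kekulize SMILES: {smiles!r}") from exc
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"SMILES has no heavy atoms: {smiles!r}")
    labels = tuple(atom.GetSymbol() for atom in mol.GetAtoms())
    A = np.zeros((n, n), dtype=np.int64)
    for bond in mol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise SmilesParseError(
                f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = order
    return MolecularGraph(atom_labels=labels, adjacency=A)


Label = "int | np.ndarray"


@dataclass
class LabeledDataset:
    """Compound records: (id, SMILES, label).

    ``label_mode`` is ``"single"`` (labels are class indices 0..10) or
    ``"multi"`` (labels are 11-entry 0/1 membership vectors).
    """

    records: list[tuple[str, str, object]]
    label_mode: str = "single"
    class_space: ClassLabelSpace = field(default_factory=ClassLabelSpace)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r[1] for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        if self.label_mode == "single":
            return np.array([r[2] for r in self.records], dtype=np.int64)
        return np.array([r[2] for r in self.records], dtype=np.int64)

    def membership_matrix(self) -> np.ndarray:
        """Labels as an (M, 11) 0/1 matrix in either mode."""
        if self.label_mode == "multi":
            return self.labels
        out = np.zeros((len(self), N_CLASSES), dtype=np.int64)
        out[np.arange(len(self)), self.labels] = 1
        return out

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            label_mode=self.label_mode,
            class_space=self.class_space,
        )


def parse_bitstring(bits: str) -> np.ndarray:
    """Parse an 11-character association bit-string into a 0/1 vector."""
    if len(bits) != N_CLASSES or any(c not in "01" for c in bits):
        raise ValueError(
            f"association bit-string must be {N_CLASSES} characters of 0/1, "
            f"got {bits!r}"
        )
    return np.array([int(c) for c in bits], dtype=np.int64)


def format_bitstring(bits: Iterable[int]) -> str:
    """Render a membership vector as an 11-character 0/1 string."""
    out = "".join("1" if int(b) else "0" for b in bits)
    if len(out) != N_CLASSES:
        raise ValueError(f"membership vector must have length {N_CLASSES}")
    return out


def read_dataset(path, label_mode: str = "single") -> LabeledDataset:
    """Read a delimited dataset file with columns id, smiles, label.

    Delimiter is sniffed from the header (comma or tab).  Rows whose SMILES
    fail to parse are skipped with a logged diagnostic; the total skip count
    is logged at the end.  Malformed labels are hard errors naming the row.
    """
    if label_mode not in ("single", "multi"):
        raise ValueError(f"label_mode must be 'single' or 'multi', got {label_mode!r}")
    with open(path, "r", newline="") as fh:
        header_line = fh.readline()
        delimiter = "\t" if "\t" in header_line else ","
        header = [c.strip() for c in header_line.rstrip("\n").split(delimiter)]
        required = {"id", "smiles", "label"}
        if not required.issubset(header):
            raise ValueError(
                f"dataset {path} missing required columns "
                f"{sorted(required - set(header))} (found {header})"
            )
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delimiter)
        records: list[tuple[str, str, object]] = []
        n_skipped = 0
        for row_no, row in enumerate(reader, start=2):
            cid = row["id"]
            smi = row["smiles"]
            raw = row["label"]
            if label_mode == "single":
                try:
                    label: object = int(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path} row {row_no}: single-class label must be an "
                        f"integer 0..{N_CLASSES - 1}, got {raw!r}"
                    )
                if not 0 <= label < N_CLASSES:
                    raise ValueError(
                        f"{path} row {row_no}: class index {label} out of range"
                    )
            else:
                try:
                    label = parse_bitstring(raw)
                except ValueError as exc:
                    raise ValueError(f"{path} row {row_no}: {exc}") from exc
            try:
                parse_smiles(smi)
            except SmilesParseError as exc:
                logger.warning("skipping row %d of %s: %s", row_no, path, exc)
                n_skipped += 1
                continue
            records.append((cid, smi, label))
    if n_skipped:
        logger.warning("skipped %d unparseable row(s) while reading %s", n_skipped, path)
        print(
            f"pathgcn: skipped {n_skipped} unparseable row(s) in {path}",
            file=sys.stderr,
        )
    return LabeledDataset(records=records, label_mode=label_mode)


def write_dataset(dataset: LabeledDataset, path) -> None:
    """Write a dataset as CSV with columns id, smiles, label (round-trips)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "label"])
        for cid, smi, label in dataset.records:
            if dataset.label_mode == "multi":
                writer.writerow([cid, smi, format_bitstring(label)])
            else:
                writer.writerow([cid, smi, int(label)])


def stratified_splits(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_repeats: int = 1,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Repeated (train, validation, test) index partitions.

    Single-class datasets are stratified by class; multi-label datasets are
    shuffled without stratification.  Classes with fewer than 3 members fall
    back to unstratified assignment (with a warning), since they cannot seed
    all three partitions.  Partitions are disjoint and exhaustive within
    each repeat, and deterministic given ``seed``.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    m = len(dataset)

    def allot(n: int) -> tuple[int, int, int]:
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        return n_train, n_val, n - n_train - n_val

    splits = []
    for _ in range(n_repeats):
        if dataset.label_mode == "single":
            labels = dataset.labels
            pool: list[int] = []  # unstratified fallback pool
            tr: list[int] = []
            va: list[int] = []
            te: list[int] = []
            for cls in np.unique(labels):
                idx = np.flatnonzero(labels == cls)
                if len(idx) < 3:
                    logger.warning(
                        "class %d has %d member(s); assigning unstratified",
                        cls,
                        len(idx),
                    )
                    pool.extend(idx.tolist())
                    continue
                idx = rng.permutation(idx)
                n_train, n_val, _ = allot(len(idx))
                tr.extend(idx[:n_train].tolist())
                va.extend(idx[n_train : n_train + n_val].tolist())
                te.extend(idx[n_train + n_val :].tolist())
            if pool:
                pool_arr = rng.permutation(np.array(pool))
                n_train, n_val, _ = allot(len(pool_arr))
                tr.extend(pool_arr[:n_train].tolist())
                va.extend(pool_arr[n_train : n_train + n_val].tolist())
                te.extend(pool_arr[n_train + n_val :].tolist())
            parts = (np.sort(tr), np.sort(va), np.sort(te))
        else:
            perm = rng.permutation(m)
            n_train, n_val, _ = allot(m)
            parts = (
                np.sort(perm[:n_train]),
                np.sort(perm[n_train : n_train + n_val]),
                np.sort(perm[n_train + n_val :]),
            )
        splits.append(parts)
    return splits
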