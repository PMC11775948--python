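"""Node-level r-radius subgraph fingerprints and global molecular features.

Each atom is assigned a canonical identifier of its r-radius subgraph — the
subgraph induced by all atoms within r bonds — via iterative
Weisfeiler–Lehman-style relabeling: round 0 is the element symbol, and each
subsequent round hashes the node's own label together with the sorted
multiset of (bond multiplicity, neighbor label) pairs.  Two atoms whose
r-hop neighborhoods are isomorphic (respecting atom labels and bond
multiplicities) therefore receive equal identifiers.

Every distinct identifier maps to a random unit-norm d-dimensional vector.
The vector is derived from a cryptographic hash of (master_seed, id), so an
identifier first seen at inference time receives the same vector it would
have received during training — no vocabulary lookup order dependence, and
embeddings are reproducible across process restarts.

The global molecular feature vector w has 173 entries: the 166 public MACCS
substructure keys plus 7 physicochemical descriptors (molecular weight,
logP, molar refractivity, rotatable bonds, ring count, aromatic ring count,
topological polar surface area).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdMolDescriptors

from .chem_io import MolecularGraph, SmilesParseError

#: Descriptor slot names, in vector order after the 166 MACCS bits.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "molecular_weight",
    "logp",
    "molar_refractivity",
    "rotatable_bonds",
    "ring_count",
    "aromatic_rings",
    "tpsa",
)

N_MACCS = 166
N_GLOBAL = N_MACCS + len(DESCRIPTOR_NAMES)  # 173

#: Names for all 173 global feature slots (used by the embedding probe).
GLOBAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"maccs_{i + 1}" for i in range(N_MACCS)
) + DESCRIPTOR_NAMES


def subgraph_ids(graph: MolecularGraph, radius: int) -> list[str]:
    """Canonical r-radius subgraph identifier for every node.

    Iterative neighborhood relabeling to depth ``radius``; identifiers are
    hex digests, stable across processes.  ``radius=0`` reduces to the atom
    label itself (hashed).
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    A = graph.adjacency
    n = graph.n_atoms
    labels = [f"atom:{s}" for s in graph.atom_labels]
    neighbors = [np.flatnonzero(A[i]) for i in range(n)]
    for _ in range(radius):
        new_labels = []
        for i in range(n):
            env = sorted((int(A[i, j]), labels[j]) for j in neighbors[i])
            payload = json.dumps([labels[i], env], separators=(",", ":"))
            new_labels.append(hashlib.sha256(payload.encode()).hexdigest()[:32])
        labels = new_labels
    # hash round-0 labels too so ids are uniform hex strings at any radius
    if radius == 0:
        labels = [
            hashlib.sha256(lab.encode()).hexdigest()[:32] for lab in labels
        ]
    return labels


def _vector_for_id(canonical_id: str, master_seed: int, dim: int) -> np.ndarray:
    """Deterministic unit-norm vector for a canonical subgraph id."""
    digest = hashlib.sha256(f"{master_seed}:{canonical_id}".encode()).digest()
    sub_seed = int.from_bytes(digest[:4], "big")
    rng = np.random.default_rng(sub_seed)
    v = rng.standard_normal(dim)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # pragma: no cover - probability ~0
        v = rng.standard_normal(dim)
        norm = np.linalg.norm(v)
    return v / norm


@dataclass
class SubgraphVocabulary:
    """Map from canonical r-radius subgraph ids to random unit-norm vectors.

    The table is a cache: vectors are a pure function of
    ``(master_seed, id, dim)``, so unseen ids at inference time are filled
    in deterministically and the same-id-same-vector invariant holds
    globally across train and inference.
    """

    radius: int = 2
    dim: int = 50
    master_seed: int = 0
    table: dict[str, np.ndarray] = field(default_factory=dict)

    def vector(self, canonical_id: str) -> np.ndarray:
        v = self.table.get(canonical_id)
        if v is None:
            v = _vector_for_id(canonical_id, self.master_seed, self.dim)
            self.table[canonical_id] = v
        return v

    def __len__(self) -> int:
        return len(self.table)

    def to_jsonable(self) -> dict:
        return {
            "radius": self.radius,
            "dim": self.dim,
            "master_seed": self.master_seed,
            "ids": sorted(self.table),
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "SubgraphVocabulary":
        vocab = cls(
            radius=int(obj["radius"]),
            dim=int(obj["dim"]),
            master_seed=int(obj["master_seed"]),
        )
        for cid in obj.get("ids", []):
            vocab.vector(cid)
        return vocab


def init_node_embeddings(
    ids: list[str], vocab: SubgraphVocabulary
) -> np.ndarray:
    """Initial node embedding matrix X(0): one unit-norm row per node."""
    if not ids:
        raise ValueError("no node ids given")
    return np.vstack([vocab.vector(cid) for cid in ids])


@dataclass(frozen=True)
class GlobalFeatureVector:
    """173-dim curated molecular property vector w.

    166 MACCS substructure key bits followed by 7 physicochemical
    descriptors covering size (molecular weight, g/mol), lipophilicity
    (logP, aromatic ring count), rigidity (rotatable bonds, ring count),
    polarizability (molar refractivity) and polarity (TPSA, Å²).
    """

    maccs: np.ndarray
    descriptors: np.ndarray

    def __post_init__(self) -> None:
        if self.maccs.shape != (N_MACCS,):
            raise ValueError(f"expected {N_MACCS} MACCS bits, got {self.maccs.shape}")
        if self.descriptors.shape != (len(DESCRIPTOR_NAMES),):
            raise ValueError(
                f"expected {len(DESCRIPTOR_NAMES)} descriptors, "
                f"got {self.descriptors.shape}"
            )

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.maccs.astype(float), self.descriptors])

    def __len__(self) -> int:
        return N_GLOBAL


def global_features(smiles: str) -> GlobalFeatureVector:
    """Compute the 173-dim global molecular feature vector for a SMILES."""
    mol = Chem.MolFromSmiles(smiles) if smiles and smiles.strip() else None
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    # rdkit MACCS keys are 167 bits with bit 0 always unset; vector slot i
    # holds public key i+1.
    fp = MACCSkeys.GenMACCSKeys(mol)
    maccs = np.zeros(N_MACCS, dtype=np.int64)
    for bit in fp.GetOnBits():
        if 1 <= bit <= N_MACCS:
            maccs[bit - 1] = 1
    descriptors = np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Crippen.MolMR(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            rdMolDescriptors.CalcTPSA(mol),
        ],
        dtype=float,
    )
    return GlobalFeatureVector(maccs=maccs, descriptors=descriptors)


def global_feature_matrix(smiles_list: list[str]) -> np.ndarray:
    """Stack global feature vectors for a list of SMILES into (M, 173)."""
    return np.vstack([global_features(s).as_array() for s in smiles_list])
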