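"""SMILES parsing, graph featurization, Morgan fingerprints, and dataset I/O.

Molecules are parsed with RDKit and re-canonicalized so that atom numbering is
deterministic for a given structure regardless of how the input SMILES was
written.  Atom and bond feature vectors follow the conventions of directed
message-passing encoders for molecular property prediction: a small element
vocabulary one-hot, heavy-atom degree, formal charge, and aromaticity for
atoms; bond-order one-hot plus ring/aromatic flags for bonds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

# --- feature vocabulary (documented configuration) -------------------------
ELEMENT_VOCAB = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + "other" slot
MAX_DEGREE = 5  # heavy-atom degree one-hot over 0..5
CHARGE_RANGE = (-2, 2)  # formal charge clipped and one-hot over 5 slots
ATOM_FEATURE_DIM = len(ELEMENT_VOCAB) + 1 + (MAX_DEGREE + 1) + 5 + 1  # 22
BOND_ORDERS = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_FEATURE_DIM = len(BOND_ORDERS) + 2  # + ring flag + aromatic flag = 6

DEFAULT_NBITS = 2048
FP_MATRIX_SHAPE = (32, 64)


class InvalidSmiles(ValueError):
    """The SMILES string does not parse to a molecule."""


class EmptyMolecule(ValueError):
    """The SMILES parses but contains zero heavy atoms."""


class LengthMismatch(ValueError):
    """Fingerprint bit-vector length does not match the expected size."""


class MissingColumn(KeyError):
    """A required column is absent from the dataset file."""


class EmptyDataset(ValueError):
    """No usable records remain after filtering."""


@dataclass
class MoleculeRecord:
    """One labelled molecule: identifier, SMILES, and a binary activity label."""

    id: str
    smiles: str
    label: int | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class MolecularGraph:
    """A molecule as atoms, bonds and directed edges (two per bond)."""

    smiles: str
    n_atoms: int
    directed_edges: list[tuple[int, int]]
    neighbor_index: list[set[int]]
    atom_features: np.ndarray | None = None  # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    mol: Chem.Mol | None = None

    @property
    def n_bonds(self) -> int:
        return len(self.directed_edges) // 2


@dataclass
class Fingerprint:
    """A binary circular fingerprint and its 2-D matrix view."""

    bits: np.ndarray  # (nbits,) uint8

    @property
    def matrix(self) -> np.ndarray:
        return reshape_fingerprint(self)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Atoms are renumbered into RDKit canonical order (via canonical-SMILES
    round-trip), so two SMILES spellings of the same molecule yield the same
    graph.  Hydrogens stay implicit.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmiles("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(f"unparseable SMILES: {smiles!r}")
    # round-trip through canonical SMILES for a deterministic atom order
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if mol.GetNumAtoms() == 0:
        raise EmptyMolecule(f"zero heavy atoms in {smiles!r}")
    n = mol.GetNumAtoms()
    directed_edges: list[tuple[int, int]] = []
    neighbor_index: list[set[int]] = [set() for _ in range(n)]
    for bond in mol.GetBonds():
        p, q = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        directed_edges.append((p, q))
        directed_edges.append((q, p))
        neighbor_index[p].add(q)
        neighbor_index[q].add(p)
    return MolecularGraph(
        smiles=smiles,
        n_atoms=n,
        directed_edges=directed_edges,
        neighbor_index=neighbor_index,
        mol=mol,
    )


def _atom_feature(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    idx = ELEMENT_VOCAB.index(sym) if sym in ELEMENT_VOCAB else len(ELEMENT_VOCAB)
    v[idx] = 1.0
    off = len(ELEMENT_VOCAB) + 1
    v[off + min(atom.GetDegree(), MAX_DEGREE)] = 1.0
    off += MAX_DEGREE + 1
    charge = int(np.clip(atom.GetFormalCharge(), *CHARGE_RANGE))
    v[off + charge - CHARGE_RANGE[0]] = 1.0
    off += 5
    v[off] = 1.0 if atom.GetIsAromatic() else 0.0
    return v


def _bond_feature(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(BOND_FEATURE_DIM)
    if bond.GetBondType() in BOND_ORDERS:
        v[BOND_ORDERS.index(bond.GetBondType())] = 1.0
    v[len(BOND_ORDERS)] = 1.0 if bond.IsInRing() else 0.0
    v[len(BOND_ORDERS) + 1] = 1.0 if bond.GetIsAromatic() else 0.0
    return v


def featurize(graph: MolecularGraph) -> MolecularGraph:
    """Populate per-atom and per-bond feature vectors in place; returns the graph.

    Elements outside the vocabulary land in a reserved "other" one-hot slot
    rather than raising.
    """
    if graph.mol is None:
        raise ValueError("graph has no RDKit molecule; use parse_smiles first")
    graph.atom_features = np.stack(
        [_atom_feature(a) for a in graph.mol.GetAtoms()]
    ) if graph.n_atoms else np.zeros((0, ATOM_FEATURE_DIM))
    graph.bond_features = {}
    for bond in graph.mol.GetBonds():
        p, q = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        graph.bond_features[(min(p, q), max(p, q))] = _bond_feature(bond)
    return graph


def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """Hashed circular (Morgan/ECFP-style) fingerprint of a molecule.

    Delegates the environment enumeration and hashing to RDKit's Morgan
    generator; radius 2 corresponds to ECFP4.  Deterministic for a given
    SMILES, radius and width.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits)


def reshape_fingerprint(fp: Fingerprint) -> np.ndarray:
    """Row-major 32x64 matrix view of a 2048-bit fingerprint.

    ``matrix[r, c] == bits[64*r + c]``; flattening the matrix row-major
    recovers the bit vector exactly.
    """
    if fp.bits.shape[0] != FP_MATRIX_SHAPE[0] * FP_MATRIX_SHAPE[1]:
        raise LengthMismatch(
            f"expected {FP_MATRIX_SHAPE[0] * FP_MATRIX_SHAPE[1]} bits, got {fp.bits.shape[0]}"
        )
    return fp.bits.reshape(FP_MATRIX_SHAPE)


def load_dataset(
    path: str | Path,
    smiles_col: str = "smiles",
    label_cols: list[str] | None = None,
) -> list[MoleculeRecord]:
    """Read a CSV (or ``.smi``) file into molecule records.

    Multi-task label columns are dichotomized with an any-active rule: the
    record label is 1 if any task label equals 1, else 0.  Rows whose SMILES
    does not parse, and rows with every label missing, are dropped with a
    logged count.  ``.smi`` files (``SMILES<TAB>id`` per line) yield unlabeled
    records for scoring.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".smi":
        records = []
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split("\t")
            smi = parts[0].strip()
            rid = parts[1].strip() if len(parts) > 1 else f"row-{i}"
            if Chem.MolFromSmiles(smi) is None:
                logger.warning("dropping unparseable SMILES at line %d", i + 1)
                continue
            records.append(MoleculeRecord(id=rid, smiles=smi, label=None))
        if not records:
            raise EmptyDataset(f"no valid molecules in {path}")
        return records

    df = pd.read_csv(path)
    if smiles_col not in df.columns:
        raise MissingColumn(f"required column {smiles_col!r} not in {list(df.columns)}")
    if label_cols is None:
        label_cols = [c for c in df.columns if c not in (smiles_col, "id")]
    missing = [c for c in label_cols if c not in df.columns]
    if missing:
        raise MissingColumn(f"label columns {missing} not in {list(df.columns)}")
    if not label_cols:
        raise MissingColumn("no label columns present")

    records: list[MoleculeRecord] = []
    n_bad_smiles = 0
    n_no_label = 0
    for i, row in df.iterrows():
        rid = str(row["id"]) if "id" in df.columns else f"row-{i}"
        smi = row[smiles_col]
        if not isinstance(smi, str) or Chem.MolFromSmiles(smi) is None:
            n_bad_smiles += 1
            continue
        labels = pd.to_numeric(row[label_cols], errors="coerce")
        if labels.isna().all():
            n_no_label += 1
            continue
        label = int((labels == 1).any())  # any-active dichotomization
        records.append(MoleculeRecord(id=rid, smiles=smi, label=label))
    if n_bad_smiles or n_no_label:
        logger.info(
            "dropped %d unparseable-SMILES and %d all-missing-label rows from %s",
            n_bad_smiles, n_no_label, path,
        )
    if not records:
        raise EmptyDataset(f"no usable records in {path}")
    return records


def save_dataset(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records to CSV in the same schema :func:`load_dataset` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)
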