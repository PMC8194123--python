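"""Morgan fingerprints, Tanimoto similarity and the drug-similarity graph.

The graph drives the graph-convolutional embedding: each drug is connected to
the ``k`` (default 40) drugs with the most similar chemical structure, the
remaining entries of its similarity row are zeroed, and the row is normalized
to edge weights summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "SimilarityGraph",
    "morgan_fingerprint",
    "tanimoto",
    "tanimoto_matrix",
    "build_similarity_graph",
]


class Fingerprint(NamedTuple):
    drug_id: str
    bits: np.ndarray  # 0/1 vector


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024,
                       drug_id: str | None = None) -> Fingerprint:
    """Hashed circular (Morgan/ECFP-style) fingerprint of a molecule.

    Radius 2 is the ECFP4 equivalent; ``n_bits`` defaults to 1024 to match
    the decoder output width of the embedding network.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        name = drug_id if drug_id is not None else smiles
        raise SmilesParseError(f"cannot parse SMILES for record {name!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return Fingerprint(drug_id=drug_id or smiles, bits=fp.astype(np.uint8))


def _bits(fp) -> np.ndarray:
    arr = np.asarray(fp.bits if isinstance(fp, Fingerprint) else fp)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("fingerprint bits must be 0/1")
    return arr.astype(np.int64)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between two bit vectors.

    Two all-zero vectors are defined to have similarity 1 (they are
    identical); this degenerate case is logged.
    """
    va, vb = _bits(a), _bits(b)
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.shape} vs {vb.shape}")
    union = int(np.count_nonzero(va | vb))
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return float(np.count_nonzero(va & vb) / union)


def tanimoto_matrix(bits: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix for an (n, fp_bits) 0/1 array."""
    b = np.asarray(bits, dtype=np.int64)
    inter = b @ b.T
    pop = b.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


@dataclass
class SimilarityGraph:
    """Row-normalized k-nearest-neighbour structure graph.

    ``weights`` is an (n, n) non-negative matrix in which row i carries the
    edge weights from drug i to its retained neighbours (at most k off the
    diagonal) plus a self-loop; every row sums to one. The matrix is not
    symmetric in general because top-k retention is row-wise.
    """

    drug_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.drug_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be (n, n) aligned with drug_ids")

    def __len__(self) -> int:
        return len(self.drug_ids)

    @classmethod
    def identity(cls, drug_ids: Sequence[str]) -> "SimilarityGraph":
        """Self-loops only: turns the graph convolution into a plain dense layer."""
        ids = list(drug_ids)
        return cls(drug_ids=ids, weights=np.eye(len(ids)))


def build_similarity_graph(fps: Sequence[Fingerprint] | np.ndarray,
                           drug_ids: Sequence[str] | None = None,
                           k: int = 40,
                           self_loop: bool = True) -> SimilarityGraph:
    """Top-k row-normalized Tanimoto similarity graph.

    Per row, the ``k`` largest similarities to *other* drugs are retained
    (all of them when n-1 <= k) and the rest zeroed; ties at the k-th rank
    break toward the lower drug index for determinism. A self-weight equal
    to the maximal similarity (1.0) is then added so each node's own
    features participate in the convolution, and the row is divided by its
    sum. A row with no nonzero similarity falls back to its self-loop alone,
    keeping the matrix row-stochastic.
    """
    if isinstance(fps, np.ndarray):
        bits = fps
        ids = list(drug_ids) if drug_ids is not None else [str(i) for i in range(len(bits))]
    else:
        fps = list(fps)
        bits = np.stack([_bits(f) for f in fps])
        ids = [f.drug_id for f in fps]
    n = len(ids)
    if n < 1:
        raise ValueError("need at least one drug")
    if k < 1:
        raise ValueError("k must be >= 1")

    sim = tanimoto_matrix(bits)
    weights = np.zeros((n, n))
    for i in range(n):
        row = sim[i].copy()
        row[i] = -np.inf  # the self entry is handled separately
        order = np.lexsort((np.arange(n), -row))  # descending sim, ties by index
        keep = [j for j in order[: min(k, n - 1)] if row[j] > 0.0]
        weights[i, keep] = sim[i, keep]
        if self_loop or not keep:
            weights[i, i] = 1.0
        weights[i] /= weights[i].sum()
    return SimilarityGraph(drug_ids=ids, weights=weights)
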