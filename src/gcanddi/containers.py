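"""In-memory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DrugTable", "DdiDataset"]

PLACEHOLDER_SMILES = "*"


@dataclass
class DrugTable:
    """A set of drugs with transcriptome signatures and (optionally) structure.

    Parameters
    ----------
    ids:
        Unique drug identifiers, in a fixed order shared by all row-aligned
        arrays in the package (similarity graphs, embeddings, ...).
    smiles:
        SMILES string per drug, or the placeholder ``"*"`` for synthetic drugs
        whose fingerprints were generated directly.
    signatures:
        ``(n_drugs, sig_dim)`` float array of differential-expression values
        of landmark genes versus control (977 genes in the L1000 convention).
    fingerprints:
        Optional ``(n_drugs, fp_bits)`` 0/1 array of structure fingerprints.
        Present for synthetic drugs; for real drugs it is derived from SMILES.
    classes:
        Optional latent structural class per drug (synthetic data only); used
        as planted ground truth in tests and experiments.
    """

    ids: list[str]
    smiles: list[str]
    signatures: np.ndarray
    fingerprints: np.ndarray | None = None
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("drug ids must be unique")
        if self.signatures.ndim != 2 or self.signatures.shape[0] != len(self.ids):
            raise ValueError("signatures must be a (n_drugs, sig_dim) matrix")
        if len(self.smiles) != len(self.ids):
            raise ValueError("smiles list must align with ids")
        if self.fingerprints is not None:
            self.fingerprints = np.asarray(self.fingerprints)
            if self.fingerprints.shape[0] != len(self.ids):
                raise ValueError("fingerprints must align with ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def sig_dim(self) -> int:
        return self.signatures.shape[1]

    def index_of(self, drug_id: str) -> int:
        try:
            return self.ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None


@dataclass
class DdiDataset:
    """Ordered drug pairs with typed interaction labels.

    ``pairs`` has columns ``drug_a``, ``drug_b``, ``type_label``; the pair
    ``(a, b)`` is ordered, so ``(b, a)`` is a distinct record. ``vocabulary``
    is the sorted list of interaction types present.
    """

    pairs: pd.DataFrame
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"drug_a", "drug_b", "type_label"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pairs frame must have columns {sorted(required)}")
        self.pairs = self.pairs.reset_index(drop=True)
        if not self.vocabulary:
            self.vocabulary = sorted(self.pairs["type_label"].unique())

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def type_counts(self) -> pd.Series:
        return self.pairs["type_label"].value_counts()
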