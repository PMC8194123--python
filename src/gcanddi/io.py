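"""Readers and writers for the package's delimited-text artifacts.

All formats are UTF-8, tab-delimited, with a header row, '.' decimal
separator and no quoting, so that write-then-read round-trips are exact and
identical inputs produce byte-identical files.

Formats
-------
drug table      drug_id, smiles, g1..g<sig_dim>
fingerprints    drug_id, b1..b<fp_bits>
DDI list        drug_a, drug_b, type_label
graph edges     source_id, target_id, weight
embeddings      drug_id, e1..e<dim>
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import SimilarityGraph
from .containers import DdiDataset, DrugTable
from .gcan import EmbeddedFeatures

__all__ = [
    "FormatError",
    "read_drug_table",
    "write_drug_table",
    "read_fingerprints",
    "write_fingerprints",
    "read_ddi_list",
    "write_ddi_list",
    "read_graph",
    "write_graph",
    "read_embeddings",
    "write_embeddings",
    "prepare_ddi_dataset",
    "PreparationReport",
    "import_l1000_signatures",
]

_FLOAT_FMT = "%.17g"  # shortest representation that round-trips float64


class FormatError(ValueError):
    pass


def _write_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                 lineterminator="\n")


# ------------------------------------------------------------------ drugs


def write_drug_table(table: DrugTable, path) -> None:
    cols = {"drug_id": table.ids, "smiles": table.smiles}
    frame = pd.DataFrame(cols)
    sig = pd.DataFrame(table.signatures,
                       columns=[f"g{i + 1}" for i in range(table.sig_dim)])
    _write_frame(pd.concat([frame, sig], axis=1), path)


def read_drug_table(path) -> DrugTable:
    frame = _read_tsv(path)
    for col in ("drug_id", "smiles"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    gene_cols = [c for c in frame.columns if c.startswith("g") and c[1:].isdigit()]
    if not gene_cols:
        raise FormatError(f"{path}: no signature columns g1..gN found")
    gene_cols.sort(key=lambda c: int(c[1:]))
    ids = frame["drug_id"].astype(str).tolist()
    dupes = frame["drug_id"][frame["drug_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate drug ids {dupes}")
    sig = frame[gene_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(sig).all(axis=1))[0]
    if bad.size:
        raise FormatError(f"{path}: non-numeric signature cells in data row {bad[0] + 1}")
    return DrugTable(ids=ids, smiles=frame["smiles"].astype(str).tolist(),
                     signatures=sig)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fingerprints(ids: list[str], bits: np.ndarray, path) -> None:
    bits = np.asarray(bits, dtype=int)
    frame = pd.DataFrame(bits, columns=[f"b{i + 1}" for i in range(bits.shape[1])])
    frame.insert(0, "drug_id", ids)
    _write_frame(frame, path)


def read_fingerprints(path) -> tuple[list[str], np.ndarray]:
    frame = _read_tsv(path)
    bit_cols = [c for c in frame.columns if c.startswith("b") and c[1:].isdigit()]
    bit_cols.sort(key=lambda c: int(c[1:]))
    return frame["drug_id"].astype(str).tolist(), frame[bit_cols].to_numpy(dtype=np.uint8)


# ------------------------------------------------------------------- ddis


def write_ddi_list(ddis: DdiDataset, path) -> None:
    _write_frame(ddis.pairs[["drug_a", "drug_b", "type_label"]], path)


def read_ddi_list(path) -> DdiDataset:
    frame = _read_tsv(path)
    for col in ("drug_a", "drug_b", "type_label"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return DdiDataset(pairs=frame[["drug_a", "drug_b", "type_label"]].astype(str))


# ------------------------------------------------------------------ graph


def write_graph(graph: SimilarityGraph, path) -> None:
    src, dst = np.nonzero(graph.weights)
    frame = pd.DataFrame(
        {
            "source_id": [graph.drug_ids[i] for i in src],
            "target_id": [graph.drug_ids[j] for j in dst],
            "weight": graph.weights[src, dst],
        }
    )
    _write_frame(frame, path)


def read_graph(path, drug_ids: list[str] | None = None) -> SimilarityGraph:
    frame = _read_tsv(path)
    ids = drug_ids if drug_ids is not None else sorted(
        set(frame["source_id"].astype(str)) | set(frame["target_id"].astype(str))
    )
    index = {d: i for i, d in enumerate(ids)}
    weights = np.zeros((len(ids), len(ids)))
    for row in frame.itertuples():
        weights[index[str(row.source_id)], index[str(row.target_id)]] = float(row.weight)
    return SimilarityGraph(drug_ids=list(ids), weights=weights)


# ------------------------------------------------------------- embeddings


def write_embeddings(features: EmbeddedFeatures, path) -> None:
    frame = pd.DataFrame(features.matrix,
                         columns=[f"e{i + 1}" for i in range(features.matrix.shape[1])])
    frame.insert(0, "drug_id", features.drug_ids)
    _write_frame(frame, path)


def read_embeddings(path, kind: str = "gcan") -> EmbeddedFeatures:
    frame = _read_tsv(path)
    cols = [c for c in frame.columns if c.startswith("e") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    return EmbeddedFeatures(drug_ids=frame["drug_id"].astype(str).tolist(),
                            matrix=frame[cols].to_numpy(dtype=float), kind=kind)


# ----------------------------------------------------- dataset preparation


@dataclass
class PreparationReport:
    """Per-step removal counts from gold-standard DDI preparation."""

    n_input: int = 0
    removed_flagged: int = 0
    removed_missing: int = 0
    removed_small_types: int = 0
    dropped_types: list[str] = field(default_factory=list)
    flagged_drugs: list[str] = field(default_factory=list)
    missing_drugs: list[str] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return (self.n_input - self.removed_flagged - self.removed_missing
                - self.removed_small_types)


def prepare_ddi_dataset(raw_pairs: pd.DataFrame | DdiDataset,
                        drug_table: DrugTable,
                        exclusions: pd.DataFrame | None = None,
                        min_pairs_per_type: int = 5,
                        ) -> tuple[DdiDataset, PreparationReport]:
    """Apply the gold-standard filters to a raw typed interaction list.

    In order: (1) drop pairs involving a drug flagged in ``exclusions``
    (columns ``drug_id`` plus boolean flags such as ``multi_ingredient`` and
    ``biologic``); (2) drop pairs involving a drug absent from the drug
    table (no transcriptome signature); (3) drop interaction types left
    with fewer than ``min_pairs_per_type`` pairs, so each surviving type can
    appear in every CV fold. Counts removed at each step are reported.
    """
    pairs = raw_pairs.pairs if isinstance(raw_pairs, DdiDataset) else raw_pairs
    pairs = pairs[["drug_a", "drug_b", "type_label"]].astype(str).reset_index(drop=True)
    report = PreparationReport(n_input=len(pairs))

    flagged: set[str] = set()
    if exclusions is not None and len(exclusions):
        flag_cols = [c for c in exclusions.columns if c != "drug_id"]
        mask = exclusions[flag_cols].astype(bool).any(axis=1)
        flagged = set(exclusions.loc[mask, "drug_id"].astype(str))
    keep = ~(pairs["drug_a"].isin(flagged) | pairs["drug_b"].isin(flagged))
    report.removed_flagged = int((~keep).sum())
    report.flagged_drugs = sorted(
        set(pairs.loc[~keep, ["drug_a", "drug_b"]].to_numpy().ravel()) & flagged
    )
    pairs = pairs[keep]

    known = set(drug_table.ids)
    keep = pairs["drug_a"].isin(known) & pairs["drug_b"].isin(known)
    report.removed_missing = int((~keep).sum())
    report.missing_drugs = sorted(
        set(pairs.loc[~keep, ["drug_a", "drug_b"]].to_numpy().ravel()) - known
    )
    pairs = pairs[keep]

    counts = pairs["type_label"].value_counts()
    small = counts[counts < min_pairs_per_type].index
    report.dropped_types = sorted(small)
    keep = ~pairs["type_label"].isin(small)
    report.removed_small_types = int((~keep).sum())
    pairs = pairs[keep].reset_index(drop=True)

    if pairs.empty:
        raise ValueError("no pairs survive gold-standard preparation")
    return DdiDataset(pairs=pairs), report


# ------------------------------------------------------ L1000 text adapter


def import_l1000_signatures(matrix_path, metadata_path, cell_line: str,
                            sig_dim: int = 977) -> DrugTable:
    """Build a drug table from pre-exported landmark-gene text matrices.

    ``matrix_path`` is a TSV with columns ``sig_id, g1..g<sig_dim>`` of
    replicate-collapsed differential expression values; ``metadata_path``
    is a TSV with columns ``sig_id, compound_id, cell_line, is_exemplar``
    (and optionally ``smiles``). Rows are filtered to the requested cell
    line and to exemplar signatures; a compound with several exemplar
    signatures gets their element-wise mean. Native GCTx/HDF5 parsing is
    intentionally not implemented — acquisition is an upstream step and
    only this documented text boundary is supported.
    """
    matrix = _read_tsv(matrix_path)
    meta = _read_tsv(metadata_path)
    gene_cols = [f"g{i + 1}" for i in range(sig_dim)]
    missing = [c for c in gene_cols if c not in matrix.columns]
    if missing:
        raise FormatError(f"{matrix_path}: missing landmark columns, first {missing[0]!r}")
    meta = meta[(meta["cell_line"].astype(str) == cell_line)
                & meta["is_exemplar"].astype(bool)]
    merged = meta.merge(matrix, on="sig_id", how="inner")
    if merged.empty:
        raise FormatError(f"no exemplar signatures for cell line {cell_line!r}")
    has_smiles = "smiles" in merged.columns
    ids, smiles, rows = [], [], []
    for compound, group in merged.groupby("compound_id", sort=True):
        ids.append(str(compound))
        smiles.append(str(group["smiles"].iloc[0]) if has_smiles else "*")
        rows.append(group[gene_cols].to_numpy(dtype=float).mean(axis=0))
    return DrugTable(ids=ids, smiles=smiles, signatures=np.vstack(rows))
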