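"""Seeded generator of synthetic drug tables and typed DDI lists.

The generator plants the statistical structure the prediction pipeline
assumes, so every downstream stage is testable without any external download:

* drugs fall into a small number of latent structural classes; each drug's
  fingerprint is its class prototype bit vector with independent per-bit
  flips (structure noise);
* the transcriptome signature is a fixed random linear map of the
  fingerprint plus Gaussian noise, so the raw structure-expression
  correlation is low at high noise but recoverable by an embedding that is
  trained to reconstruct structure;
* the interaction type of an ordered drug pair is a deterministic function
  of the two latent classes, and every emitted type keeps at least
  ``pairs_per_type_min`` pairs (mirroring the gold-standard filter that
  drops under-populated interaction types).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PLACEHOLDER_SMILES, DdiDataset, DrugTable

__all__ = ["SimulationConfig", "simulate_drugs", "simulate_ddis", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe a small three-class cohort with mild structure noise
    and unit expression noise; dimensions follow the L1000/Morgan convention
    (977 landmark genes, 1024 fingerprint bits).
    """

    n_drugs: int = 60
    n_classes: int = 3
    fp_bits: int = 1024
    sig_dim: int = 977
    bit_flip_rate: float = 0.05
    expr_noise_sd: float = 1.0
    n_types: int = 4
    pairs_per_type_min: int = 5
    n_pairs: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs <= 0:
            raise ValueError("n_drugs must be positive")
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if self.n_classes > self.n_drugs:
            raise ValueError("n_classes cannot exceed n_drugs")
        if not (0.0 <= self.bit_flip_rate <= 1.0):
            raise ValueError("bit_flip_rate must be a probability")
        if self.expr_noise_sd < 0.0:
            raise ValueError("expr_noise_sd must be non-negative")
        if self.pairs_per_type_min < 5:
            raise ValueError(
                "pairs_per_type_min must be >= 5 (five-fold CV requires every "
                "type to appear in every fold)"
            )
        if self.n_types <= 0 or self.n_types > 80:
            raise ValueError("n_types must be in 1..80")
        if self.n_types > self.n_classes**2:
            raise ValueError(
                "n_types exceeds the number of ordered class pairs "
                f"({self.n_classes}^2); types are a function of class pairs"
            )


def _id_width(n: int) -> int:
    return max(4, len(str(n)))


def simulate_drugs(config: SimulationConfig) -> DrugTable:
    """Generate a drug table with planted class structure.

    Class prototypes are Bernoulli(0.5) bit vectors; each drug copies its
    prototype with per-bit flips at ``bit_flip_rate``. Signatures are
    ``fingerprint @ M / sqrt(fp_bits) * 4 + noise`` with a fixed
    seed-determined Gaussian map ``M``, giving per-gene signal of order one
    so that ``expr_noise_sd`` is interpretable as a signal-to-noise dial.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    prototypes = rng.integers(0, 2, size=(config.n_classes, config.fp_bits))
    classes = np.sort(rng.integers(0, config.n_classes, size=config.n_drugs))
    # guarantee every class is populated
    classes[: config.n_classes] = np.arange(config.n_classes)

    flips = rng.random((config.n_drugs, config.fp_bits)) < config.bit_flip_rate
    fingerprints = np.where(flips, 1 - prototypes[classes], prototypes[classes])

    mixing = rng.standard_normal((config.fp_bits, config.sig_dim))
    signal = fingerprints @ mixing / np.sqrt(config.fp_bits) * 4.0
    noise = rng.standard_normal((config.n_drugs, config.sig_dim)) * config.expr_noise_sd
    signatures = signal + noise

    width = _id_width(config.n_drugs)
    ids = [f"D{i:0{width}d}" for i in range(config.n_drugs)]
    return DrugTable(
        ids=ids,
        smiles=[PLACEHOLDER_SMILES] * config.n_drugs,
        signatures=signatures,
        fingerprints=fingerprints.astype(np.uint8),
        classes=classes,
    )


def interaction_type_of(class_a: int, class_b: int, config: SimulationConfig) -> str:
    """Deterministic map from an ordered latent-class pair to a type label."""
    code = (class_a * config.n_classes + class_b) % config.n_types
    return f"T{code:02d}"


def simulate_ddis(drugs: DrugTable, config: SimulationConfig) -> DdiDataset:
    """Sample unique ordered pairs and label them from the latent classes.

    Types that end up with fewer than ``pairs_per_type_min`` pairs are
    dropped, mirroring the preparation filter applied to real interaction
    lists before five-fold cross-validation.
    """
    config.validate()
    if drugs.classes is None:
        raise ValueError("drug table lacks latent classes; generate it with simulate_drugs")
    n = len(drugs)
    if n < 2:
        raise ValueError("need at least two drugs to form ordered pairs")
    n_possible = n * (n - 1)
    n_pairs = config.n_pairs if config.n_pairs is not None else min(
        n_possible, max(40 * config.n_types, 200)
    )
    if n_pairs > n_possible:
        raise ValueError(f"cannot draw {n_pairs} unique ordered pairs from {n} drugs")

    # derive an independent stream so drug and pair sampling do not interact
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    codes = rng.choice(n_possible, size=n_pairs, replace=False)
    a_idx = codes // (n - 1)
    b_off = codes % (n - 1)
    b_idx = np.where(b_off >= a_idx, b_off + 1, b_off)  # skip the diagonal

    labels = [
        interaction_type_of(int(drugs.classes[a]), int(drugs.classes[b]), config)
        for a, b in zip(a_idx, b_idx)
    ]
    frame = pd.DataFrame(
        {
            "drug_a": [drugs.ids[i] for i in a_idx],
            "drug_b": [drugs.ids[i] for i in b_idx],
            "type_label": labels,
        }
    )
    counts = frame["type_label"].value_counts()
    keep = counts[counts >= config.pairs_per_type_min].index
    frame = frame[frame["type_label"].isin(keep)].reset_index(drop=True)
    if frame.empty:
        raise ValueError(
            "no interaction type reached pairs_per_type_min; increase n_pairs"
        )
    return DdiDataset(pairs=frame)


def simulate_dataset(config: SimulationConfig) -> tuple[DrugTable, DdiDataset]:
    """Convenience wrapper generating drugs and their typed pairs together."""
    drugs = simulate_drugs(config)
    return drugs, simulate_ddis(drugs, config)
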