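"""Similarity-profile correlation diagnostics.

A drug can be represented by its vector of similarities to every drug in the
cohort (its *similarity profile*). Computing, per drug, the Pearson
correlation between its profile under one feature space (e.g. raw or embedded
transcriptome signatures, compared with inverse-squared-distance similarity)
and under another (e.g. Tanimoto structure similarity) quantifies how well
the feature space mirrors chemical structure. The embedding is expected to
raise this correlation relative to raw signatures.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chem import tanimoto_matrix

__all__ = [
    "euclidean_similarity",
    "similarity_matrix",
    "profile_correlation",
]


def euclidean_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Inverse-squared-distance similarity 1 / (sum_i (x_i - y_i)^2 + 1).

    Lies in (0, 1]; equals 1 exactly when the vectors coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(1.0 / (np.sum((x - y) ** 2) + 1.0))


def similarity_matrix(features: np.ndarray, kind: str = "euclidean") -> np.ndarray:
    """Pairwise drug-similarity matrix (symmetric, unit diagonal).

    ``kind='euclidean'`` uses the inverse-squared-distance similarity for
    real-valued features; ``kind='tanimoto'`` expects 0/1 fingerprints.
    """
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a (n>=2, d) feature matrix")
    if kind == "euclidean":
        sq = squareform(pdist(features.astype(float), metric="sqeuclidean"))
        return 1.0 / (sq + 1.0)
    if kind == "tanimoto":
        return tanimoto_matrix(features)
    raise ValueError(f"unknown similarity kind {kind!r}")


def profile_correlation(profiles_a: np.ndarray, profiles_b: np.ndarray,
                        exclude_self: bool = True):
    """Per-drug Pearson correlation between two similarity-profile sets.

    Both arguments are (n, n) similarity matrices over the same drug
    ordering. For each drug i, the correlation is computed between row i of
    the two matrices. The self-similarity entry (identically 1 in both
    spaces) is excluded by default so a constant shared point does not
    inflate the correlation. A zero-variance row yields NaN and is excluded
    from the median.

    Returns
    -------
    r : (n,) array of per-drug correlations (NaN where undefined)
    median : median of the defined correlations
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("profile sets must be two (n, n) matrices with equal shape")
    n = a.shape[0]
    r = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        if exclude_self:
            mask[i] = False
        x, y = a[i, mask], b[i, mask]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            continue
        r[i] = float(np.mean(x * y) - x.mean() * y.mean()) / (sx * sy)
    defined = r[~np.isnan(r)]
    median = float(np.median(defined)) if defined.size else float("nan")
    return r, median
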