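"""Fingerprint similarity model: exact-match prefix, Soergel and Hamming metrics.

Two layered count fingerprints are compared in three stages.  First an exact
match of the top layers (the root layer counts as the first) rejects pairs
whose immediate environments differ.  Surviving pairs get a per-layer Soergel
dissimilarity d_j (the complement of the count-Tanimoto coefficient, in
[0, 1]) and a per-layer Hamming distance (sum of absolute count differences).
The total score is the layer-weighted sum

    d_total = sum_j  Δλ_{j+1} · d_j · d_Ham,j

with a weighting coefficient that decays with layer depth,

    Δλ = (2 / λ_total) · [ λ / e^(λ−1)  +  (λ_total − 1) / (2λ) ],   λ = j + 1.

d_total is 0 for identical fingerprints and unbounded above.  A pair is
*similar* when the exact-match prefix holds and d_total does not exceed the
threshold (3.5 by default, with the top three layers matched exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fingerprint import N_LAYERS, FingerprintMatrix

DEFAULT_EXACT_DEPTH = 3
DEFAULT_THRESHOLD = 3.5


@dataclass(frozen=True)
class SimilarityParams:
    """Tunable knobs of the similarity decision."""

    exact_depth: int = DEFAULT_EXACT_DEPTH
    threshold: float = DEFAULT_THRESHOLD
    n_layers: int = N_LAYERS

    def __post_init__(self) -> None:
        if not 0 <= self.exact_depth <= self.n_layers:
            raise ValueError("exact_depth must be in [0, n_layers]")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass(frozen=True)
class SimilarityScore:
    per_layer_soergel: tuple[float, ...]
    per_layer_hamming: tuple[int, ...]
    weights: tuple[float, ...]
    total: float
    exact_prefix_ok: bool


def layer_weight(lam: int, lam_total: int = N_LAYERS) -> float:
    """Weighting coefficient Δλ for layer index λ (1-based; λ=1 is the root)."""
    if lam < 1:
        raise ValueError("layer index λ must be >= 1")
    return (2.0 / lam_total) * (lam / math.exp(lam - 1) + (lam_total - 1) / (2.0 * lam))


def soergel_layer(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Soergel dissimilarity between two count rows, in [0, 1].

    0 iff the rows are equal, 1 iff their supports are disjoint.  The sum
    runs over the full alphabet width.
    """
    a = np.asarray(row_a, dtype=np.float64)
    b = np.asarray(row_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"row width mismatch: {a.shape} vs {b.shape}")
    num = float(np.dot(a, b))
    den = float(np.sum(a * a + b * b - a * b))
    if den == 0.0:  # both rows empty; padding normally rules this out
        return 0.0
    return 1.0 - num / den


def hamming_layer(row_a: np.ndarray, row_b: np.ndarray) -> int:
    """Count-form Hamming distance: sum of absolute per-column differences."""
    a = np.asarray(row_a, dtype=np.int64)
    b = np.asarray(row_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError(f"row width mismatch: {a.shape} vs {b.shape}")
    return int(np.abs(a - b).sum())


def total_distance(fp_a: FingerprintMatrix, fp_b: FingerprintMatrix,
                   params: SimilarityParams | None = None) -> SimilarityScore:
    """Weighted total score of all layers, plus the exact-prefix flag."""
    params = params or SimilarityParams()
    a, b = fp_a.counts, fp_b.counts
    if a.shape != b.shape:
        raise ValueError(f"fingerprint shape mismatch: {a.shape} vs {b.shape}")
    soergel, hamming, weights = [], [], []
    total = 0.0
    for j in range(a.shape[0]):
        d_j = soergel_layer(a[j], b[j])
        h_j = hamming_layer(a[j], b[j])
        w_j = layer_weight(j + 1, a.shape[0])
        soergel.append(d_j)
        hamming.append(h_j)
        weights.append(w_j)
        total += w_j * d_j * h_j
    prefix_ok = bool(np.array_equal(a[: params.exact_depth], b[: params.exact_depth]))
    return SimilarityScore(tuple(soergel), tuple(hamming), tuple(weights),
                           total, prefix_ok)


def is_similar(fp_a: FingerprintMatrix, fp_b: FingerprintMatrix,
               params: SimilarityParams | None = None) -> bool:
    """Similarity decision: exact prefix holds and total <= threshold (inclusive)."""
    params = params or SimilarityParams()
    score = total_distance(fp_a, fp_b, params)
    return score.exact_prefix_ok and score.total <= params.threshold
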