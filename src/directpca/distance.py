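"""Pairwise distances between encoded sequences and the distance-matrix PCA baseline.

Two distances are computed from the one-hot rows x⃗:

* ê = √(Σ(x⃗₁ − x⃗₂)²/2) — Euclidean length, halved inside the root because a
  substitution changes two indicator coordinates (one symbol gained, one
  lost).  For unambiguous data ê² equals the raw mismatch count.
* p̂ = Σ|x⃗₁ − x⃗₂|/2l — the substitution rate: the fraction of aligned
  positions at which the two sequences differ; ê = √(p̂·l).

The JC69 map d̂ = −¾·ln(1 − 4p̂/3) converts p̂ to an evolutionary distance.

:func:`conventional_pca` is the comparison baseline: PCA applied to the
pairwise ê matrix rather than to the sequence matrix itself, with the extra
1/√2 because the square matrix records every distance twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .direct_pca import Jc69SaturationError, _fix_signs, RANK_TOL
from .seq_matrix import SequenceMatrix

__all__ = [
    "DistanceMatrix",
    "ConventionalPcaResult",
    "pairwise_distances",
    "jc69_distance",
    "conventional_pca",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances: ``euclid`` holds ê, ``prate`` holds p̂."""

    euclid: np.ndarray
    prate: np.ndarray
    ids: list[str]
    l: int  # noqa: E741

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ConventionalPcaResult:
    """Sample scores and contributions of PCA on the ê distance matrix."""

    scores: np.ndarray  # (n, r), already divided by √2·√l
    singular_values: np.ndarray
    ids: list[str]

    @property
    def contributions(self) -> np.ndarray:
        total = self.singular_values.sum()
        if total == 0:
            return np.empty(0)
        return 100.0 * self.singular_values / total


def pairwise_distances(X: SequenceMatrix) -> DistanceMatrix:
    """All-pairs ê and p̂ for the rows of a sequence matrix."""
    if X.n < 2:
        raise ValueError("pairwise distances need at least two samples")
    euclid = squareform(pdist(X.values, metric="euclidean") / np.sqrt(2.0))
    prate = squareform(pdist(X.values, metric="cityblock") / (2.0 * X.l))
    return DistanceMatrix(euclid, prate, list(X.ids), X.l)


def jc69_distance(p):
    """JC69 evolutionary distance d̂ = −¾·ln(1 − 4p̂/3) for p̂ in [0, 3/4).

    Accepts a scalar or array; raises :class:`Jc69SaturationError` at or
    beyond the saturation point p̂ = 3/4.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= 0.75):
        raise Jc69SaturationError(
            "substitution rate must lie in [0, 0.75); the JC69 distance "
            "diverges at saturation"
        )
    d = -0.75 * np.log1p(-4.0 * p_arr / 3.0)
    return float(d) if np.isscalar(p) else d


def conventional_pca(
    dm: DistanceMatrix, double_center: bool = False
) -> ConventionalPcaResult:
    """PCA of the ê distance matrix — the baseline the direct method replaces.

    The square ê matrix is column-mean centered (``double_center=True``
    additionally removes row means, PCoA-style), factored by SVD, and the
    sample scores S = LΣ are divided by √2 (each distance appears in both
    triangles) and by √l, putting them on the same sPC scale as the direct
    method.
    """
    E = np.asarray(dm.euclid, dtype=float)
    if E.shape[0] != E.shape[1] or not np.allclose(E, E.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if dm.n < 2:
        raise ValueError("conventional PCA needs at least two samples")
    centered = E - E.mean(axis=0, keepdims=True)
    if double_center:
        centered = centered - centered.mean(axis=1, keepdims=True)
    L, sigma, Rt = np.linalg.svd(centered, full_matrices=False)
    r = int(np.sum(sigma > RANK_TOL * sigma[0])) if sigma.size and sigma[0] > 0 else 0
    # sign convention shared with the direct method, applied to the L columns
    R, L = _fix_signs(Rt[:r].T.copy(), L[:, :r].copy())
    scores = (L * sigma[:r]) / (np.sqrt(2.0) * np.sqrt(dm.l))
    return ConventionalPcaResult(scores, sigma[:r].copy(), list(dm.ids))
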