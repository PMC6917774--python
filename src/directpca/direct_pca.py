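"""Direct PCA of the one-hot sequence matrix.

The centered matrix D (rows = samples minus a center sequence) is factored by
singular value decomposition, D = LΣRᵀ.  Sample components are S = LΣ = DR
and base components are N = RΣ = DᵀL; both are rotations of D, so distances
between samples are preserved exactly.  Scaling by the alignment length and
sample count, Ŝ = S/√l and N̂ = N/√n, puts scores from different studies on a
common footing (the sPC scale).  The contribution of an axis is its singular
value as a percentage of the total.

An optional per-sample rescaling compensates multiple substitutions at one
site under the one-parameter Markov model of Jukes and Cantor (JC69): the raw
divergence of a sample from the center, p̂ = Σ|d|/2l, is mapped to the
evolutionary distance d̂ = −¾·ln(1 − 4p̂/3), and the row is stretched by
√(d̂/p̂) ≥ 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import Alphabet
from .seq_matrix import SequenceMatrix

__all__ = [
    "CenterVector",
    "CenteredMatrix",
    "PcaResult",
    "CharacteristicBases",
    "Jc69SaturationError",
    "compute_center",
    "center_matrix",
    "jc69_adjust",
    "run_direct_pca",
    "project_samples",
    "characteristic_bases",
    "group_dispersion",
]

#: Singular values below this fraction of the largest are treated as zero.
RANK_TOL = 1e-12


class Jc69SaturationError(ValueError):
    """Raised when a divergence p̂ ≥ 3/4 leaves the JC69 model undefined."""


@dataclass
class CenterVector:
    """Center of rotation m: a length k·l vector of per-column means.

    ``source`` records how it was obtained: the string ``"mean"`` (all
    samples) or the list of reference ids averaged.
    """

    values: np.ndarray
    source: str | list[str]
    l: int  # noqa: E741
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.alphabet.k * self.l,):
            raise ValueError("center length does not match k*l")


@dataclass
class CenteredMatrix:
    """The matrix D of per-sample deviations from the center sequence.

    ``adjusted`` flags JC69 compensation; ``compensation_ratios`` holds each
    sample's d̂/p̂ (all 1.0 when unadjusted).
    """

    values: np.ndarray
    ids: list[str]
    l: int  # noqa: E741
    alphabet: Alphabet
    adjusted: bool = False
    compensation_ratios: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.compensation_ratios is None:
            self.compensation_ratios = np.ones(len(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PcaResult:
    """SVD factors and the derived (scaled) principal components.

    Components are truncated to the effective rank r (singular values below
    ``RANK_TOL`` times the largest dropped); with mean centering r ≤ n − 1.
    A deterministic sign convention is applied: each right-singular column is
    flipped so its largest-magnitude entry (first such entry on ties) is
    positive, with the matching left column flipped jointly.
    """

    left_vectors: np.ndarray  # L, (n, r)
    singular_values: np.ndarray  # Σ diagonal, (r,)
    right_vectors: np.ndarray  # R, (k·l, r)
    l: int  # noqa: E741
    n: int
    ids: list[str]
    alphabet: Alphabet

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    @property
    def sample_components(self) -> np.ndarray:
        """S = LΣ = DR."""
        return self.left_vectors * self.singular_values

    @property
    def base_components(self) -> np.ndarray:
        """N = RΣ = DᵀL."""
        return self.right_vectors * self.singular_values

    @property
    def scaled_sample_components(self) -> np.ndarray:
        """Ŝ = S/√l, the sPC scores for samples."""
        return self.sample_components / np.sqrt(self.l)

    @property
    def scaled_base_components(self) -> np.ndarray:
        """N̂ = N/√n, the sPC loadings for bases."""
        return self.base_components / np.sqrt(self.n)

    @property
    def contributions(self) -> np.ndarray:
        """Each singular value as a percentage of the total (sums to 100)."""
        total = self.singular_values.sum()
        if total == 0:
            return np.empty(0)
        return 100.0 * self.singular_values / total

    def base_index(self) -> list[tuple[int, str]]:
        """(1-based position, symbol) labels for the k·l base coordinates."""
        return [
            (j + 1, sym)
            for sym in self.alphabet.symbols
            for j in range(self.l)
        ]


@dataclass
class CharacteristicBases:
    """Bases whose sPC loading on one axis exceeds a magnitude threshold."""

    axis: int  # 1-based, matching the sPC label
    threshold: float
    positive_bases: list[tuple[int, str, float]]  # (position, symbol, score)
    negative_bases: list[tuple[int, str, float]]


def compute_center(
    X: SequenceMatrix, reference_ids: Sequence[str] | None = None
) -> CenterVector:
    """Column means of the sequence matrix, over all samples or a reference set.

    The mean center is the usual choice; a reference subset centers the
    rotation on chosen samples so that the remaining samples are read as
    deviations from that reference group.
    """
    if reference_ids is None:
        values = X.values.mean(axis=0)
        source: str | list[str] = "mean"
    else:
        reference_ids = list(reference_ids)
        if not reference_ids:
            raise ValueError("reference_ids must name at least one sample")
        unknown = [r for r in reference_ids if r not in X.ids]
        if unknown:
            raise ValueError(f"reference ids not in the alignment: {unknown}")
        rows = [X.ids.index(r) for r in reference_ids]
        values = X.values[rows].mean(axis=0)
        source = reference_ids
    return CenterVector(values, source, X.l, X.alphabet)


def center_matrix(X: SequenceMatrix, m: CenterVector) -> CenteredMatrix:
    """Subtract the center from every row: D with rows d = x − m."""
    if m.values.shape[0] != X.values.shape[1] or m.l != X.l:
        raise ValueError("center vector does not match matrix dimensions")
    return CenteredMatrix(X.values - m.values, list(X.ids), X.l, X.alphabet)


def _jc69_ratio(p: np.ndarray) -> np.ndarray:
    """Compensation ratio d̂/p̂, with the p̂→0 limit fixed to 1."""
    p = np.asarray(p, dtype=float)
    ratio = np.ones_like(p)
    nz = p > 0
    ratio[nz] = -0.75 * np.log1p(-4.0 * p[nz] / 3.0) / p[nz]
    return ratio


def jc69_adjust(D: CenteredMatrix) -> CenteredMatrix:
    """Rescale each row of D by √(d̂/p̂) to the JC69 evolutionary distance.

    Rows with p̂ = 0 are left unchanged (ratio 1 by continuity); a row with
    p̂ ≥ 3/4 raises :class:`Jc69SaturationError` naming the sample.
    """
    if D.adjusted:
        raise ValueError("matrix is already JC69-adjusted")
    p_hat = np.abs(D.values).sum(axis=1) / (2.0 * D.l)
    saturated = np.flatnonzero(p_hat >= 0.75)
    if saturated.size:
        names = [D.ids[i] for i in saturated]
        raise Jc69SaturationError(
            f"JC69 saturation: p̂ ≥ 3/4 for sample(s) {names}; the "
            "evolutionary distance is undefined at this divergence"
        )
    ratios = _jc69_ratio(p_hat)
    values = D.values * np.sqrt(ratios)[:, None]
    return CenteredMatrix(
        values, list(D.ids), D.l, D.alphabet, adjusted=True, compensation_ratios=ratios
    )


def _fix_signs(L: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip (L, R) column pairs so R's largest-|entry| (first on ties) is > 0."""
    for j in range(R.shape[1]):
        col = R[:, j]
        lead = np.argmax(np.abs(col))
        if col[lead] < 0:
            R[:, j] = -col
            L[:, j] = -L[:, j]
    return L, R


def run_direct_pca(D: CenteredMatrix) -> PcaResult:
    """Thin SVD of the centered matrix with deterministic signs.

    Requires n ≥ 2.  A matrix with no variation at all returns an empty
    (rank-0) result and warns rather than raising.
    """
    if D.n < 2:
        raise ValueError("direct PCA needs at least two samples")
    L, sigma, Rt = np.linalg.svd(D.values, full_matrices=False)
    if sigma.size == 0 or sigma[0] == 0:
        warnings.warn("no variation among sequences; PCA result is empty")
        r = 0
    else:
        r = int(np.sum(sigma > RANK_TOL * sigma[0]))
    L, R = _fix_signs(L[:, :r].copy(), Rt[:r].T.copy())
    return PcaResult(
        left_vectors=L,
        singular_values=sigma[:r].copy(),
        right_vectors=R,
        l=D.l,
        n=D.n,
        ids=list(D.ids),
        alphabet=D.alphabet,
    )


def project_samples(
    X_new: SequenceMatrix, m: CenterVector, result: PcaResult
) -> np.ndarray:
    """Project new samples onto an existing rotation: (X − m)·R/√l.

    Classification of unknowns then amounts to reading their coordinates in
    the reference frame; projecting the training samples reproduces Ŝ.
    """
    if X_new.l != result.l or X_new.alphabet != result.alphabet:
        raise ValueError(
            "query alignment does not match the fitted model "
            f"(l={X_new.l} vs {result.l}, alphabet {X_new.alphabet.name} "
            f"vs {result.alphabet.name})"
        )
    return (X_new.values - m.values) @ result.right_vectors / np.sqrt(result.l)


def characteristic_bases(
    result: PcaResult, axis: int, threshold: float
) -> CharacteristicBases:
    """Bases distinguishing the sample groups separated by one axis.

    ``axis`` is 1-based (axis 1 = sPC1).  Returns the (position, symbol,
    score) triples whose N̂ loading exceeds ``threshold`` in magnitude, split
    by sign and ordered by position.  Bases with null loadings on every axis
    are the conserved bases and never appear here.
    """
    if not 1 <= axis <= result.rank:
        raise ValueError(f"axis {axis} out of range (rank {result.rank})")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    scores = result.scaled_base_components[:, axis - 1]
    labels = result.base_index()
    positive = [
        (pos, sym, float(s))
        for (pos, sym), s in zip(labels, scores)
        if s > threshold
    ]
    negative = [
        (pos, sym, float(s))
        for (pos, sym), s in zip(labels, scores)
        if s < -threshold
    ]
    positive.sort(key=lambda t: (t[0], t[1]))
    negative.sort(key=lambda t: (t[0], t[1]))
    return CharacteristicBases(axis, threshold, positive, negative)


def group_dispersion(
    X: SequenceMatrix, groups: Mapping[str, str] | None = None
) -> tuple[dict[str, float], float]:
    """Within-group dispersion on the sPC scale, per group and overall.

    For a group with members x_i and center m_g (the group mean vector) the
    statistic is sqrt(mean_i ê(x_i, m_g)² / l): the root-mean-square distance
    of members from their group center, scaled by the alignment length so it
    is comparable to sPC scores.  The total uses the single all-samples
    group.  ``groups`` maps sample id → group label and must cover every
    sample exactly once; ``None`` computes only the total.
    """

    def rms_stat(rows: np.ndarray) -> float:
        center = rows.mean(axis=0)
        e_sq = ((rows - center) ** 2).sum(axis=1) / 2.0  # ê² per member
        return float(np.sqrt(e_sq.mean() / X.l))

    total = rms_stat(X.values)
    per_group: dict[str, float] = {}
    if groups is not None:
        missing = [i for i in X.ids if i not in groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        labels = sorted({groups[i] for i in X.ids})
        for g in labels:
            rows = X.values[[i for i, sid in enumerate(X.ids) if groups[sid] == g]]
            if rows.shape[0] == 0:
                raise ValueError(f"group {g!r} has no members")
            per_group[g] = rms_stat(rows)
    return per_group, total
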