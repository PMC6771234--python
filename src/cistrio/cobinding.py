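"""Combinatorial co-binding classification of anchor sites (S-codes) and
non-negative matrix factorization of binding-signal matrices.

An S-code is a binary membership string over an ordered factor list: with
factor order (GATA3, NR2F2, FOXA1), code ``110`` marks an anchor site
overlapped by GATA3 and NR2F2 peaks but not FOXA1. Codes partition the
anchor cistrome; cardinality coverage summarizes how much of it is bound
by one, two, ... or none of the factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, overlap_flags, count_overlapping

__all__ = [
    "CombinationTable",
    "NMFResult",
    "classify_combinations",
    "combination_classes_as_sitesets",
    "pairwise_overlap_matrix",
    "nmf_binding",
]


@dataclass
class CombinationTable:
    """Per-site S-codes of an anchor cistrome over k factor cistromes."""

    anchor: PeakSet
    factor_order: tuple[str, ...]
    codes: np.ndarray  # per-site code strings, aligned with anchor.df rows
    group_counts: dict[str, int] = field(default_factory=dict)
    coverage_by_cardinality: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.factor_order)

    @property
    def covered_fraction(self) -> float:
        """Fraction of anchor sites bound by at least one factor."""
        return 1.0 - self.coverage_by_cardinality.get(0, 0.0)

    def marginal_fraction(self, factor: str) -> float:
        """Fraction of anchor sites whose code sets this factor's bit."""
        i = self.factor_order.index(factor)
        return float(np.mean([c[i] == "1" for c in self.codes]))

    def to_frame(self) -> pd.DataFrame:
        df = self.anchor.df[["chrom", "start", "end"]].copy()
        df["code"] = self.codes
        return df


def classify_combinations(
    anchor: PeakSet, factors: Sequence[PeakSet], min_bp: int = 1
) -> CombinationTable:
    """Assign each anchor site its S-code over the given factor order.

    Bit i is 1 iff the site overlaps factor i by at least ``min_bp``
    (Boolean membership: multiple overlapping intervals of one factor
    still set the bit once). The all-zero code counts as uncovered.
    """
    k = len(factors)
    if not 1 <= k <= 8:
        raise ValueError("need between 1 and 8 factor peak sets")
    labels = [f.label for f in factors]
    if len(set(labels)) != k:
        raise ValueError(f"duplicate factor labels: {labels}")
    bits = np.column_stack(
        [overlap_flags(anchor, f, min_bp) for f in factors]
    ).astype(np.uint8)
    codes = np.array(["".join("1" if b else "0" for b in row) for row in bits])
    n = len(anchor)
    uniq, counts = np.unique(codes, return_counts=True)
    group_counts = {str(c): int(m) for c, m in zip(uniq, counts)}
    card = bits.sum(axis=1)
    coverage = {
        int(c): (float(np.sum(card == c) / n) if n else 0.0) for c in range(k + 1)
    }
    return CombinationTable(anchor, tuple(labels), codes, group_counts, coverage)


def combination_classes_as_sitesets(table: CombinationTable) -> dict[str, PeakSet]:
    """Split the anchor into one PeakSet per observed S-code.

    The classes are pairwise disjoint and their union is the anchor set;
    they feed per-group signal profiles and the super-enhancer screen.
    """
    out: dict[str, PeakSet] = {}
    for code in sorted(table.group_counts):
        mask = table.codes == code
        out[code] = table.anchor.subset(mask, label=f"{table.anchor.label}:S{code}")
    return out


def pairwise_overlap_matrix(
    factors: Sequence[PeakSet], min_bp: int = 1
) -> pd.DataFrame:
    """k x k matrix of overlap percentages between factor cistromes.

    Entry (i, j) is the percentage of factor i's peaks overlapped by
    factor j; rows need not sum to anything and the matrix is not
    symmetric. The diagonal is 100 by construction.
    """
    if len(factors) < 2:
        raise ValueError("need at least 2 factor peak sets")
    for f in factors:
        if len(f) == 0:
            raise ValueError(f"empty peak set: {f.label}")
    labels = [f.label for f in factors]
    mat = np.zeros((len(factors), len(factors)))
    for i, fi in enumerate(factors):
        for j, fj in enumerate(factors):
            mat[i, j] = 100.0 * count_overlapping(fi, fj, min_bp) / len(fi)
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class NMFResult:
    """Outcome of a multiplicative-update non-negative factorization.

    ``basis`` (W, sites x rank) holds putative binding "complexes";
    ``coefficients`` (H, rank x factors) holds each factor's weight in
    each complex — the matrix visualized to read off co-binding structure.
    """

    basis: np.ndarray
    coefficients: np.ndarray
    rank: int
    reconstruction_error: float
    error_history: np.ndarray  # Frobenius error after each iteration

    def __post_init__(self) -> None:
        if (self.basis < 0).any() or (self.coefficients < 0).any():
            raise ValueError("NMF factors must be nonnegative")


def nmf_binding(
    matrix: np.ndarray,
    rank: int,
    max_iter: int = 2000,
    tol: float = 1e-10,
    seed: int = 0,
    n_init: int = 1,
) -> NMFResult:
    """Factor a nonnegative site x factor signal matrix as V ~ W @ H.

    Multiplicative updates minimizing the Frobenius error; the error is
    non-increasing across iterations. ``n_init`` random restarts (seeded,
    so the result is deterministic) guard against poor local minima; the
    best factorization is returned. ``tol`` is the relative per-iteration
    error improvement below which the update loop stops.
    """
    V = np.asarray(matrix, dtype=float)
    if V.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if (V < 0).any():
        raise ValueError("matrix entries must be nonnegative")
    if rank <= 0:
        raise ValueError("rank must be positive")
    if rank >= min(V.shape):
        raise ValueError(
            f"rank must be < min(n_sites, n_factors) = {min(V.shape)}"
        )
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    eps = 1e-12
    norm_v = np.linalg.norm(V)
    init_scale = np.sqrt(max(V.mean(), eps) / rank)
    best: NMFResult | None = None
    for _ in range(n_init):
        W = init_scale * (rng.random((V.shape[0], rank)) + 0.01)
        H = init_scale * (rng.random((rank, V.shape[1])) + 0.01)
        errors = []
        prev = np.inf
        for _it in range(max_iter):
            H *= (W.T @ V) / (W.T @ W @ H + eps)
            W *= (V @ H.T) / (W @ (H @ H.T) + eps)
            err = float(np.linalg.norm(V - W @ H))
            errors.append(err)
            if prev - err < tol * max(norm_v, 1.0):
                break
            prev = err
        result = NMFResult(W, H, rank, errors[-1], np.asarray(errors))
        if best is None or result.reconstruction_error < best.reconstruction_error:
            best = result
    assert best is not None
    return best
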