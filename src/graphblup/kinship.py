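"""Genomic relationship and similarity matrices.

Two kernels drive the prediction models: the VanRaden genomic
relationship matrix G (method 1: centred dosages, scaled by total
expected heterozygosity) and, downstream in :mod:`graphblup.graph`, the
network kernel GA = AAT. This module also provides the pairwise
allele-matching similarity used to build graphs, and its complement
distance d = 1 - s.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MarkerMatrix

__all__ = [
    "RelationshipKernel",
    "SimilarityMatrix",
    "DistanceMatrix",
    "vanraden_g",
    "genomic_similarity",
    "similarity_to_distance",
    "write_kernel",
    "read_kernel",
]

_SYM_TOL = 1e-10
_PSD_TOL = -1e-8


@dataclass(frozen=True)
class RelationshipKernel:
    """Symmetric PSD n x n covariance kernel over lines."""

    line_ids: list[str]
    K: np.ndarray
    kind: str  # "vanraden_G" | "graph_GA"

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "K", K)
        if K.ndim != 2 or K.shape[0] != K.shape[1] or K.shape[0] != len(self.line_ids):
            raise ValueError("kernel must be square and match line_ids")
        if np.abs(K - K.T).max() > _SYM_TOL:
            raise ValueError("kernel not symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise allele-matching similarity, entries in [0, 1], unit diagonal."""

    line_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.shape != (len(self.line_ids),) * 2:
            raise ValueError("similarity must be square and match line_ids")
        if np.abs(S - S.T).max() > _SYM_TOL:
            raise ValueError("similarity not symmetric")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        if np.abs(np.diag(S) - 1).max() > 1e-12:
            raise ValueError("similarity diagonal must be 1")


@dataclass(frozen=True)
class DistanceMatrix:
    """d(i, i') = 1 - s(i, i'); zero diagonal."""

    line_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        if D.shape != (len(self.line_ids),) * 2:
            raise ValueError("distance must be square and match line_ids")


def vanraden_g(m: MarkerMatrix) -> RelationshipKernel:
    """VanRaden (method 1) genomic relationship matrix.

    G = W W' / (2 sum_j p_j (1 - p_j)) with W = X - 2P, where p_j is the
    sample allele frequency of marker j. Rows and columns of G sum to
    zero because W's columns are centred.
    """
    if m.has_missing:
        raise ValueError("impute missing dosages before computing G")
    X = m.dosages
    p_hat = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p_hat * (1.0 - p_hat))
    if denom <= 0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = X - 2.0 * p_hat
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0  # exact symmetry against fp round-off
    return RelationshipKernel(list(m.line_ids), G, "vanraden_G")


def genomic_similarity(m: MarkerMatrix) -> SimilarityMatrix:
    """Allele-matching similarity s(i,i') = (1/p) sum_j (1 - 0.5|x_ij - x_i'j|).

    Despite being referred to as a genomic "correlation" in parts of the
    literature, this is a matching proportion, not Pearson's r: identical
    dosage vectors score 1, fully opposite homozygotes score 0.
    """
    if m.has_missing:
        raise ValueError("impute missing dosages before computing similarity")
    X = m.dosages
    n, p = X.shape
    if p == 0:
        raise ValueError("no markers")
    # sum_j |x_ij - x_i'j| via cityblock distances, then affine transform
    from scipy.spatial.distance import pdist, squareform

    manhattan = squareform(pdist(X, metric="cityblock"))
    S = 1.0 - 0.5 * manhattan / p
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(list(m.line_ids), S)


def similarity_to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    D = 1.0 - s.S
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(s.line_ids), D)


def write_kernel(k: RelationshipKernel, path: str | Path) -> None:
    """Kernel as CSV with line-id header row/column; full double precision.

    Values are written in shortest round-trip repr, so read_kernel
    recovers them bit-exactly.
    """
    df = pd.DataFrame(k.K, index=k.line_ids, columns=k.line_ids)
    df.index.name = "line_id"
    df.to_csv(path)


def read_kernel(path: str | Path, kind: str = "vanraden_G") -> RelationshipKernel:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return RelationshipKernel([str(i) for i in df.index], df.to_numpy(dtype=float), kind)
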