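"""Genotype graphs and the network kernel GA = AAT.

Two sparsification rules turn the pairwise similarity structure into a
binary adjacency matrix A over lines:

* **thresholding** — connect pairs whose similarity meets or exceeds the
  empirical quantile (default 0.65) of the n(n-1)/2 unique pairwise
  similarities; symmetric by construction;
* **k-nearest neighbours** — connect each line to its k (default 10)
  closest lines under d = 1 - s; directed, so A may be asymmetric.

Either way the diagonal is zero (no self-loops) and the implied
covariance of total network effects is GA = AAT, which is PSD
regardless of A's symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import DistanceMatrix, RelationshipKernel, SimilarityMatrix

__all__ = [
    "AdjacencyMatrix",
    "threshold_adjacency",
    "knn_adjacency",
    "graph_kernel",
    "write_edge_list",
]


@dataclass(frozen=True)
class AdjacencyMatrix:
    line_ids: list[str]
    A: np.ndarray  # (n, n) of {0, 1}
    method: str  # "threshold" | "knn"
    params: dict

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.shape != (len(self.line_ids),) * 2:
            raise ValueError("adjacency must be square and match line_ids")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.diag(A).any():
            raise ValueError("adjacency diagonal must be zero (no self-loops)")

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())

    def out_degrees(self) -> np.ndarray:
        return self.A.sum(axis=1)


def threshold_adjacency(s: SimilarityMatrix, quantile_level: float = 0.65) -> AdjacencyMatrix:
    """Connect pairs whose similarity >= the empirical quantile threshold.

    The threshold tau_c is the linear-interpolation (R type 7) quantile
    of the strictly-lower-triangle similarities; ties at tau_c are
    edges. The result is symmetric with a zero diagonal.
    """
    S = s.S
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 lines")
    if not 0.0 < quantile_level < 1.0:
        raise ValueError("quantile_level must be in (0, 1)")
    pairs = S[np.tril_indices(n, k=-1)]
    tau = float(np.quantile(pairs, quantile_level))  # numpy default = R type 7
    A = (S >= tau).astype(float)
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix(list(s.line_ids), A, "threshold", {"quantile_level": quantile_level, "tau": tau})


def knn_adjacency(d: DistanceMatrix, k: int = 10) -> AdjacencyMatrix:
    """Directed k-nearest-neighbour graph under the given distance matrix.

    Each line is connected to the k other lines with smallest distance
    (self excluded); every row of A sums to exactly k. Distance ties are
    broken by ascending line index, so the construction is deterministic.
    """
    D = np.asarray(d.D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    # stable sort on each row: equal distances resolve to lower line index
    order = np.argsort(work, axis=1, kind="stable")
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    A[rows, order[:, :k].ravel()] = 1.0
    return AdjacencyMatrix(list(d.line_ids), A, "knn", {"k": k})


def graph_kernel(a: AdjacencyMatrix, scale: bool = False) -> RelationshipKernel:
    """Network kernel GA = A A'.

    Diagonal entry i is line i's out-degree (= k for a KNN graph). With
    ``scale=True`` GA is divided by its mean diagonal (sensitivity
    analysis only; the default pipeline uses GA unscaled).
    """
    A = a.A
    GA = A @ A.T
    GA = (GA + GA.T) / 2.0
    if scale:
        md = float(np.diag(GA).mean())
        if md > 0:
            GA = GA / md
    return RelationshipKernel(list(a.line_ids), GA, "graph_GA")


def write_edge_list(a: AdjacencyMatrix, path: str | Path) -> None:
    """Edges as TSV ``from_id<TAB>to_id``, row-major order."""
    src, dst = np.nonzero(a.A)
    ids = a.line_ids
    pd.DataFrame({"from_id": [ids[i] for i in src], "to_id": [ids[j] for j in dst]}).to_csv(
        path, sep="\t", index=False
    )
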