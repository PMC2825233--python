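"""Markov clustering (MCL) of a weighted undirected graph.

Flow simulation on the graph: make the adjacency matrix column-stochastic
(after adding self-loops), then alternate expansion (matrix squaring) and
inflation (entrywise power followed by column renormalization), pruning
negligible entries, until the matrix stops changing.  Flow concentrates
within clusters; the clusters are read off the converged matrix as connected
components of its non-zero structure.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import csgraph


def mcl_partition(
    matrix: np.ndarray,
    inflation: float = 1.5,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> list[list[int]]:
    """Cluster node indices of a dense non-negative adjacency matrix.

    Self-loops are set to each node's maximum incident edge weight (1.0 for
    isolated nodes) before normalization.  Returns a partition of
    ``range(n)``; a non-converged run warns and uses the last iterate.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if (A < 0).any():
        raise ValueError("edge weights must be non-negative")
    n = A.shape[0]
    if n == 0:
        return []
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(A, loop)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        previous = M
        M = M @ M                      # expansion
        M = np.power(M, inflation)     # inflation
        M[M < prune_threshold] = 0.0
        colsums = M.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        M = M / colsums
        if previous.shape == M.shape and np.abs(M - previous).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge in {max_iter} iterations; using last iterate")
    # clusters: connected components of the non-zero structure of the limit
    support = (M + M.T) > prune_threshold
    n_comp, labels = csgraph.connected_components(support, directed=False)
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    return sorted(clusters.values(), key=lambda c: (-len(c), c))
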