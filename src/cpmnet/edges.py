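"""Edge-universe indexing helpers.

The edge universe of an ``n``-node connectome is the strict upper triangle
of the symmetric node-by-node matrix: ``n*(n-1)/2`` unordered node pairs.
All modules share the row-major upper-triangle ordering produced by
:func:`numpy.triu_indices`, so an "edge index" is a position in that fixed
enumeration.
"""

from __future__ import annotations

import numpy as np


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs (diagonal excluded)."""
    return n_nodes * (n_nodes - 1) // 2


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column node indices of each edge, in canonical order."""
    return np.triu_indices(n_nodes, k=1)


def sym_to_vec(mat: np.ndarray) -> np.ndarray:
    """Extract the strict upper triangle of a square (stack of) matrix."""
    n = mat.shape[-1]
    if mat.shape[-2] != n:
        raise ValueError(f"matrix is not square: {mat.shape}")
    i, j = edge_index(n)
    return mat[..., i, j]


def vec_to_sym(vec: np.ndarray, n_nodes: int, diag: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix (zero diagonal by default) from an edge vector."""
    e = n_edges(n_nodes)
    vec = np.asarray(vec)
    if vec.shape[-1] != e:
        raise ValueError(f"expected {e} edges for {n_nodes} nodes, got {vec.shape[-1]}")
    i, j = edge_index(n_nodes)
    out = np.full(vec.shape[:-1] + (n_nodes, n_nodes), diag, dtype=vec.dtype)
    out[..., i, j] = vec
    out[..., j, i] = vec
    return out
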