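"""Model-anatomy summaries: node degree, overlap, bilateral symmetry,
edgewise correlation vectors, and canonical-network contributions.

These operations characterize *where* a trained model's edges live rather
than how well it predicts. Degree counts edges incident to each node;
overlap compares two models' edge sets (shared / unique, the Jaccard
fraction); bilateral symmetry correlates a degree map with its
opposite-hemisphere homologs; and the contribution matrix asks which pairs
of canonical networks supply more edges than their size alone would
predict — the count of model edges between networks A and B, as a fraction
of all model edges, divided by the fraction of the whole edge universe
that lies between A and B. A value of 1 means proportionate contribution;
values above 1 mark disproportionately recruited network pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .edges import edge_index, n_edges
from .io import NodeAtlas


def node_degree(mask: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Binary node degree: masked edges incident to each node.

    Accepts either a boolean edge vector (with ``n_nodes``) or a symmetric
    diagonal-free indicator matrix. The handshake identity
    ``degree.sum() == 2 * mask.sum()`` holds for every mask.
    """
    mask = np.asarray(mask)
    if mask.ndim == 2:
        if mask.shape[0] != mask.shape[1]:
            raise ValueError("mask matrix must be square")
        if np.diagonal(mask).any():
            raise ValueError("mask matrix must be diagonal-free")
        if not np.array_equal(mask, mask.T):
            raise ValueError("mask matrix must be symmetric")
        return np.asarray(mask, bool).sum(axis=1).astype(int)
    if n_nodes is None:
        raise ValueError("n_nodes is required for an edge-vector mask")
    if mask.shape != (n_edges(n_nodes),):
        raise ValueError("edge vector length does not match n_nodes")
    i, j = edge_index(n_nodes)
    deg = np.zeros(n_nodes, int)
    sel = np.asarray(mask, bool)
    np.add.at(deg, i[sel], 1)
    np.add.at(deg, j[sel], 1)
    return deg


@dataclass
class SimilarityScore:
    r_s: float
    flagged: bool = False  # constant input: correlation undefined


def degree_similarity(d1: np.ndarray, d2: np.ndarray) -> SimilarityScore:
    """Spearman correlation (midranks) between two degree vectors."""
    d1, d2 = np.asarray(d1, float), np.asarray(d2, float)
    if d1.shape != d2.shape:
        raise ValueError("degree vectors must share the node universe")
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        return SimilarityScore(0.0, flagged=True)
    return SimilarityScore(float(stats.spearmanr(d1, d2).statistic))


def edge_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Percent overlap of two edge sets: shared edges over unique edges
    (|A ∩ B| / |A ∪ B| × 100). CN and AN are compared separately by the
    caller. Both masks empty → NaN."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the edge universe")
    union = (a | b).sum()
    if union == 0:
        return float("nan")
    return 100.0 * float((a & b).sum()) / float(union)


# ---------------------------------------------------------------------------
# Bilateral symmetry
# ---------------------------------------------------------------------------

@dataclass
class HomologMap:
    """Opposite-hemisphere homolog of each node, by reflected-centroid
    nearest neighbor."""

    homolog: dict[int, int]  # node_id -> homolog node_id
    distance: dict[int, float]  # node_id -> distance to reflected homolog (mm)


def build_homolog_map(atlas: NodeAtlas, axis: int = 0) -> HomologMap:
    """Assign each node its opposite-hemisphere homolog.

    The opposite hemisphere's centroids are reflected over the midline
    (the coordinate on ``axis`` — by convention the first, left-right axis
    with midline at 0 — is negated) and the nearest reflected centroid is
    taken as the homolog. The mapping may be many-to-one. Only covered
    nodes participate; a hemisphere with no covered nodes is an error.
    """
    cent = atlas.centroids
    hemi = atlas.hemispheres
    ids = atlas.node_ids
    cov = atlas.covered
    homolog: dict[int, int] = {}
    distance: dict[int, float] = {}
    for side, other in (("L", "R"), ("R", "L")):
        src = np.where((hemi == side) & cov)[0]
        dst = np.where((hemi == other) & cov)[0]
        if len(src) == 0 or len(dst) == 0:
            raise ValueError(f"hemisphere {other if len(dst) == 0 else side} has no covered nodes")
        refl = cent[dst].copy()
        refl[:, axis] = -refl[:, axis]
        d = np.linalg.norm(cent[src][:, None, :] - refl[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        for k, s in enumerate(src):
            homolog[int(ids[s])] = int(ids[dst[nearest[k]]])
            distance[int(ids[s])] = float(d[k, nearest[k]])
    return HomologMap(homolog, distance)


def bilateral_symmetry(
    degree: np.ndarray, homolog_map: HomologMap, atlas: NodeAtlas
) -> dict[str, SimilarityScore]:
    """Spearman correlation of node degree across hemispheres.

    Returns the left-to-right correlation (each left node's degree against
    its right homolog's degree) and the right-to-left analog.
    """
    degree = np.asarray(degree, float)
    if degree.shape != (atlas.n_nodes,):
        raise ValueError("degree vector does not match the atlas")
    ids = atlas.node_ids
    pos = {int(nid): k for k, nid in enumerate(ids)}
    hemi = atlas.hemispheres
    out: dict[str, SimilarityScore] = {}
    for key, side in (("left_to_right", "L"), ("right_to_left", "R")):
        own, their = [], []
        for nid, hom in homolog_map.homolog.items():
            if hemi[pos[nid]] == side:
                own.append(degree[pos[nid]])
                their.append(degree[pos[hom]])
        own_a, their_a = np.array(own), np.array(their)
        if len(own_a) < 3 or np.ptp(own_a) == 0 or np.ptp(their_a) == 0:
            out[key] = SimilarityScore(0.0, flagged=True)
        else:
            out[key] = SimilarityScore(float(stats.spearmanr(own_a, their_a).statistic))
    return out


# ---------------------------------------------------------------------------
# Edgewise correlation vectors
# ---------------------------------------------------------------------------

def edgewise_trait_vector(
    stack_or_edges, trait: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """Thresholding-free per-edge trait-correlation vector (1 x e), for
    comparing trait-related edge distributions across conditions without
    imposing an edge-selection cutoff."""
    from .cpm import edge_trait_association
    from .io import ConnectivityStack

    edges = (
        stack_or_edges.edge_matrix()
        if isinstance(stack_or_edges, ConnectivityStack)
        else np.asarray(stack_or_edges, float)
    )
    r, _ = edge_trait_association(edges, trait, covariates)
    return r


def vector_similarity(v1: np.ndarray, v2: np.ndarray) -> SimilarityScore:
    """Spearman similarity between two edgewise correlation vectors."""
    return degree_similarity(v1, v2)


# ---------------------------------------------------------------------------
# Canonical-network contribution
# ---------------------------------------------------------------------------

@dataclass
class ContributionMatrix:
    """Network-pair contribution of one edge mask.

    ``contribution[A-1, B-1] = (m_AB / m_tot) / (E_AB / E_tot)`` where
    ``m_AB`` counts model edges between canonical networks A and B,
    ``E_AB`` counts all possible such node pairs among covered nodes, and
    the ``tot`` values sum over unordered network pairs. Network pairs with
    no possible edges get contribution 0.
    """

    contribution: np.ndarray  # (K, K) symmetric
    model_counts: np.ndarray  # m_AB
    universe_counts: np.ndarray  # E_AB
    m_tot: int
    e_tot: int
    flagged: bool = False  # empty mask: contribution undefined


def network_contribution(
    mask: np.ndarray, networks: np.ndarray, n_networks: int = 10
) -> ContributionMatrix:
    """Size-normalized canonical-network-pair contribution of an edge mask.

    Parameters
    ----------
    mask
        Boolean edge vector over the strict upper triangle of the covered
        node universe.
    networks
        Canonical-network label (1..``n_networks``) per node of that
        universe.
    """
    networks = np.asarray(networks, int)
    n_nodes = len(networks)
    mask = np.asarray(mask, bool)
    if mask.shape != (n_edges(n_nodes),):
        raise ValueError("mask length does not match the node universe")
    if networks.min() < 1 or networks.max() > n_networks:
        raise ValueError(f"network labels must lie in 1..{n_networks}")

    i, j = edge_index(n_nodes)
    a = np.minimum(networks[i], networks[j]) - 1
    b = np.maximum(networks[i], networks[j]) - 1

    e_counts = np.zeros((n_networks, n_networks), int)
    np.add.at(e_counts, (a, b), 1)
    m_counts = np.zeros((n_networks, n_networks), int)
    np.add.at(m_counts, (a[mask], b[mask]), 1)

    m_tot = int(mask.sum())
    e_tot = int(n_edges(n_nodes))
    contrib = np.zeros((n_networks, n_networks))
    flagged = m_tot == 0
    if not flagged:
        nz = e_counts > 0
        contrib[nz] = (m_counts[nz] / m_tot) / (e_counts[nz] / e_tot)
    # mirror to full symmetric matrices
    for arr in (e_counts, m_counts, contrib):
        upper = np.triu(arr, k=1)
        arr += upper.T.astype(arr.dtype)
    return ContributionMatrix(contrib, m_counts, e_counts, m_tot, e_tot, flagged)
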