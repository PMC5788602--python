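"""Super-cluster positive augmentation.

Diseases and miRNAs are agglomerated into "super" entities by Ward-linkage
hierarchical clustering on the distance ``1 - similarity``.  A disease is
associated with a super-miRNA if it is associated with at least one member,
and that augmented association is kept only if at least one of the disease's
k nearest neighbor diseases shares it (a consistency filter against spurious
unions).  The super-association matrices are then scored with the same RLS
solve as the base layer.

The Ward linkage is computed with the Lance-Williams recurrence applied
directly to the supplied dissimilarities (treated on the squared-distance
scale, as Ward requires).  Ties in the merge criterion are broken by merging
the lexicographically smallest eligible cluster pair, where a cluster is
identified by the smallest original index of its members — this makes the
merge sequence fully deterministic.  Note the input need not be Euclidean-
embeddable; the recurrence is applied to ``1 - similarity`` as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import AssociationMatrix, SimilarityMatrix
from .rls import RLSParams, hat_matrix

__all__ = [
    "ClusterParams",
    "SuperAssociation",
    "SuperScores",
    "ward_linkage",
    "ward_cluster",
    "build_super_associations",
    "super_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterParams:
    """Dendrogram cut and neighbor-filter parameters.

    cut_height_fraction
        The tree is cut at this fraction of the maximum merge height
        (default 0.70); merges at or below the cut survive.  Ignored when
        ``n_clusters`` is given.
    n_clusters
        Explicit flat cluster count (mutually exclusive alternative to the
        fractional cut).
    k_neighbors
        Neighbor count of the super-association consistency filter
        (default 5).
    """

    cut_height_fraction: float = 0.70
    n_clusters: int | None = None
    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.cut_height_fraction <= 1.0):
            raise ValueError("cut_height_fraction must lie in (0, 1]")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class SuperAssociation:
    """Cluster assignments plus the two binary super-association matrices."""

    disease_cluster_of: dict[str, int]
    mirna_cluster_of: dict[str, int]
    Asr: np.ndarray  # nd x n_super_mirna
    Asd: np.ndarray  # n_super_disease x nm
    #: pre-filter matrices, kept for ablation / inspection
    Asr_unfiltered: np.ndarray = field(default=None, repr=False)
    Asd_unfiltered: np.ndarray = field(default=None, repr=False)

    @property
    def n_super_mirna(self) -> int:
        return self.Asr.shape[1]

    @property
    def n_super_disease(self) -> int:
        return self.Asd.shape[0]


@dataclass
class SuperScores:
    """RLS scores of the super layer.

    ``disease_to_super_mirna`` is nd x n_sr; ``super_disease_to_mirna`` is
    n_sd x nm.  Plain arrays: the axes are super entities, not named
    diseases/miRNAs.
    """

    disease_to_super_mirna: np.ndarray
    super_disease_to_mirna: np.ndarray


def ward_linkage(distances: np.ndarray) -> list[tuple[int, int, float, int]]:
    """Ward agglomeration of a symmetric dissimilarity matrix.

    Returns the merge list ``(i, j, height, new_size)`` where ``i < j`` are
    cluster keys (smallest original member index); after a merge the combined
    cluster keeps key ``i``.  Heights follow the Lance-Williams recurrence

        d(ij, k) = [(ni+nk) d(i,k) + (nj+nk) d(j,k) - nk d(i,j)] / (ni+nj+nk)

    and are non-decreasing along the sequence (Ward is reducible).
    """
    D = np.array(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or np.abs(D - D.T).max(initial=0.0) > 1e-10:
        raise ValueError("distance matrix must be square and symmetric")
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    merges: list[tuple[int, int, float, int]] = []
    for _ in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        # first occurrence of the minimum in row-major order is the
        # lexicographically smallest eligible (i, j) pair
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        height = masked[i, j]
        ni, nj = sizes[i], sizes[j]
        k_mask = active.copy()
        k_mask[[i, j]] = False
        nk = sizes[k_mask]
        new_d = ((ni + nk) * work[i, k_mask] + (nj + nk) * work[j, k_mask] - nk * height) / (
            ni + nj + nk
        )
        work[i, k_mask] = new_d
        work[k_mask, i] = new_d
        sizes[i] = ni + nj
        active[j] = False
        merges.append((i, j, float(height), int(sizes[i])))
    return merges


def _flat_partition(
    n: int, merges: list[tuple[int, int, float, int]], keep: int
) -> np.ndarray:
    """Apply the first ``keep`` merges; relabel clusters 0..k-1 by smallest member."""
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _, _ in merges[:keep]:
        ri, rj = find(i), find(j)
        parent[max(ri, rj)] = min(ri, rj)
    reps = np.array([find(x) for x in range(n)])
    _, labels = np.unique(reps, return_inverse=True)
    return labels


def ward_cluster(
    S: SimilarityMatrix, params: ClusterParams | None = None
) -> tuple[dict[str, int], list[tuple[int, int, float, int]]]:
    """Flat Ward partition of a similarity matrix at distance ``1 - S``.

    Returns (entity name -> cluster id, merge list).  With the fractional
    cut, merges with height <= fraction * max height survive; heights are
    monotone so the surviving merges are a prefix of the sequence.
    """
    params = params or ClusterParams()
    n = S.n
    if n < 2:
        logger.warning("fewer than 2 entities: returning a single cluster")
        return {name: 0 for name in S.names}, []
    D = 1.0 - S.values
    np.fill_diagonal(D, 0.0)
    merges = ward_linkage(D)
    if params.n_clusters is not None:
        keep = max(0, n - params.n_clusters)
    else:
        h_max = merges[-1][2]
        cut = params.cut_height_fraction * h_max
        keep = sum(1 for m in merges if m[2] <= cut)
    labels = _flat_partition(n, merges, keep)
    return {name: int(lab) for name, lab in zip(S.names, labels)}, merges


def _cluster_indicator(cluster_of: dict[str, int], names: list[str]) -> np.ndarray:
    """n_entities x n_clusters binary membership matrix."""
    missing = [n for n in names if n not in cluster_of]
    if missing:
        raise ValueError(f"entities missing from partition: {missing[:5]}")
    n_clusters = max(cluster_of[n] for n in names) + 1
    ind = np.zeros((len(names), n_clusters), dtype=np.int8)
    for row, name in enumerate(names):
        ind[row, cluster_of[name]] = 1
    return ind


def _knn_lists(sim: SimilarityMatrix, k: int) -> np.ndarray:
    """Indices of each entity's k nearest neighbors (self excluded).

    Neighbors are ordered by descending similarity with ties broken by name
    order; returns an (n x min(k, n-1)) index array.
    """
    n = sim.n
    k = min(k, n - 1)
    order_names = np.argsort(np.array(sim.names, dtype=object), kind="stable")
    rank_by_name = np.empty(n, dtype=int)
    rank_by_name[order_names] = np.arange(n)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        cand = [j for j in range(n) if j != i]
        cand.sort(key=lambda j: (-sim.values[i, j], rank_by_name[j]))
        neighbors[i] = cand[:k]
    return neighbors


def build_super_associations(
    A: AssociationMatrix,
    disease_partition: dict[str, int],
    mirna_partition: dict[str, int],
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    params: ClusterParams | None = None,
    apply_filter: bool = True,
) -> SuperAssociation:
    """Union associations into super entities, then apply the k-NN filter.

    ``Asr[i, q] = 1`` iff disease i is associated with >= 1 member of
    super-miRNA q; the entry is removed again if none of disease i's
    ``k_neighbors`` nearest neighbors (by integrated disease similarity)
    carries the same *pre-filter* super-association, making the filter
    order-independent.  ``Asd`` is built and filtered symmetrically on the
    miRNA side.
    """
    params = params or ClusterParams()
    ind_m = _cluster_indicator(mirna_partition, A.mirna_names)
    ind_d = _cluster_indicator(disease_partition, A.disease_names)
    Asr_raw = ((A.values @ ind_m) > 0).astype(np.int8)  # nd x n_sr
    Asd_raw = ((ind_d.T @ A.values) > 0).astype(np.int8)  # n_sd x nm
    Asr, Asd = Asr_raw.copy(), Asd_raw.copy()
    if apply_filter:
        nbr_d = _knn_lists(disease_sim, params.k_neighbors)
        support = Asr_raw[nbr_d].any(axis=1)  # nd x n_sr: any neighbor has it
        Asr = (Asr_raw & support).astype(np.int8)
        nbr_m = _knn_lists(mirna_sim, params.k_neighbors)
        support_m = Asd_raw[:, nbr_m].any(axis=2)  # n_sd x nm
        Asd = (Asd_raw & support_m).astype(np.int8)
    return SuperAssociation(
        disease_cluster_of=dict(disease_partition),
        mirna_cluster_of=dict(mirna_partition),
        Asr=Asr,
        Asd=Asd,
        Asr_unfiltered=Asr_raw,
        Asd_unfiltered=Asd_raw,
    )


def super_scores(
    SD: SimilarityMatrix,
    SR: SimilarityMatrix,
    SA: SuperAssociation,
    params: RLSParams | None = None,
) -> SuperScores:
    """RLS scores of the super layer (same solve as the base classifier)."""
    params = params or RLSParams()
    Hd = hat_matrix(SD.values, params.lambda_d)
    Hr = hat_matrix(SR.values, params.lambda_r)
    # disease x super-miRNA: SD_i (SD + lambda I)^{-1} Asr[:, q]
    d2sr = Hd.T @ SA.Asr.astype(float)
    # super-disease x miRNA: SR_j (SR + lambda I)^{-1} Asd[p, :]
    sd2m = SA.Asd.astype(float) @ Hr
    return SuperScores(disease_to_super_mirna=d2sr, super_disease_to_mirna=sd2m)
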