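"""Mobility profiles: clustering binarized monthly occupancy patterns.

Selected users of a target zone are described by 12-dimensional binary
vectors (in/out of the zone per month).  Pairwise Jaccard distance — one
minus intersection over union of the presence months — quantifies pattern
dissimilarity, and agglomerative hierarchical clustering of the distance
matrix, cut at k clusters, yields the zone's mobility profiles.  Each
profile's monthly in-zone count curve (and its z-scored signature) is the
seasonal fingerprint of one behavioral group.

Average linkage is the default; complete linkage behaves near-identically
on well-separated groups.  Ward linkage is also offered for parity with
common practice, but note it is applied to a non-Euclidean (Jaccard)
distance matrix, where its variance interpretation does not hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .popcount import zscore
from .selection import BinaryProfileMatrix

__all__ = [
    "MobilityProfileSet",
    "jaccard_distance",
    "jaccard_matrix",
    "hierarchical_profiles",
    "profile_curves",
]

LINKAGES = ("average", "complete", "ward")


def jaccard_distance(a, b) -> float:
    """1 − |a∧b| / |a∨b| for two equal-length binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors have different lengths")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    inter = np.logical_and(a, b).sum()
    return float(1.0 - inter / union)


def jaccard_matrix(B: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between the rows of a binary matrix."""
    X = np.asarray(B, dtype=bool)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero row: Jaccard distance undefined")
    Xi = X.astype(np.int64)
    inter = Xi @ Xi.T
    sizes = Xi.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class MobilityProfileSet:
    """Cluster labels and per-cluster seasonal curves for one target zone."""

    target_zone: object
    k: int
    labels: np.ndarray           # (n_users,) in 1..k; 1 = largest cluster
    user_ids: np.ndarray
    curves: np.ndarray           # (k, 12) members present per month
    signatures: np.ndarray       # (k, 12) z-scored curves
    linkage_method: str
    linkage_matrix: np.ndarray   # scipy linkage encoding of the dendrogram
    cophenetic_correlation: float

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def hierarchical_profiles(B: BinaryProfileMatrix, k: int,
                          linkage: str = "average") -> MobilityProfileSet:
    """Cluster binary profiles into k groups by Jaccard + linkage.

    The dendrogram is cut to k clusters; labels are reassigned by
    decreasing cluster size (ties by smallest first-member row index).
    Duplicate rows (distance 0) merge first by construction.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    X = B.values
    n = X.shape[0]
    n_distinct = np.unique(X, axis=0).shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct profiles")

    if n == 1:
        Z = np.empty((0, 4))
        raw = np.array([1])
        coph = 1.0
    else:
        D = jaccard_matrix(X)
        condensed = squareform(D, checks=False)
        Z = hierarchy.linkage(condensed, method=linkage)
        # cut after exactly n-k merges: always yields k clusters, even when
        # merge heights tie (fcluster's maxclust can collapse past k on ties)
        raw = hierarchy.cut_tree(Z, n_clusters=k).ravel() + 1
        coph = float(np.corrcoef(hierarchy.cophenet(Z), condensed)[0, 1]) \
            if n > 2 and condensed.std() > 0 else 1.0

    # relabel by decreasing size; tie-break on earliest member row
    ids = np.unique(raw)
    order = sorted(ids, key=lambda c: (-(raw == c).sum(),
                                       int(np.flatnonzero(raw == c)[0])))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.asarray([remap[c] for c in raw])

    k_eff = len(ids)
    curves = np.zeros((k_eff, X.shape[1]), dtype=np.int64)
    for c in range(1, k_eff + 1):
        curves[c - 1] = X[labels == c].sum(axis=0)
    return MobilityProfileSet(target_zone=B.target_zone, k=k_eff,
                              labels=labels, user_ids=B.user_ids,
                              curves=curves, signatures=zscore(curves),
                              linkage_method=linkage, linkage_matrix=Z,
                              cophenetic_correlation=coph)


def profile_curves(profile_set: MobilityProfileSet,
                   B: BinaryProfileMatrix) -> np.ndarray:
    """Recompute per-cluster monthly in-zone counts from labels and B."""
    X = B.values
    curves = np.zeros((profile_set.k, X.shape[1]), dtype=np.int64)
    for c in range(1, profile_set.k + 1):
        curves[c - 1] = X[profile_set.labels == c].sum(axis=0)
    return curves
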