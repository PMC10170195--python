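"""Protein maps and per-ROI spatial statistics.

After counting, each localization cluster is partitioned into its N protein
positions with k-means; proteins are then grouped into protein clusters
(minimum size three) and the per-ROI summary statistics computed: protein
and cluster densities, percentage of clustered proteins, small/medium/large
cluster counts, median equivalent cluster diameter and median
first-neighbour distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import KMeans

#: Protein-cluster size classes: fewer than 6 proteins is small, 6-12
#: (inclusive) medium, more than 12 large.  A cluster needs >= 3 members.
SIZE_CLASS_BOUNDS = {"small": (3, 5), "medium": (6, 12), "large": (13, None)}

MIN_CLUSTER_SIZE = 3


def kmeans_partition(
    cluster_locs: np.ndarray, n_proteins: int, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """Partition a cluster's localizations into ``n_proteins`` positions.

    k-means with k = N (k-means++ initialisation, ``n_init`` restarts, best
    inertia kept) returns the k centroids as protein positions;
    deterministic given ``seed``.  When fewer localizations than proteins
    are available the overall centroid is replicated, with a warning.
    """
    pts = np.asarray(cluster_locs, dtype=float).reshape(-1, 2)
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if len(pts) == 0:
        raise ValueError("cannot partition an empty localization set")
    if n_proteins == 1:
        return pts.mean(axis=0, keepdims=True)
    if len(pts) < n_proteins:
        warnings.warn(
            f"{len(pts)} localizations < {n_proteins} proteins; replicating centroid",
            stacklevel=2,
        )
        return np.tile(pts.mean(axis=0), (n_proteins, 1))
    km = KMeans(n_clusters=n_proteins, n_init=n_init, random_state=seed)
    km.fit(pts)
    return km.cluster_centers_


def group_proteins(
    positions: np.ndarray,
    parent_ids: np.ndarray,
    linking_radius: Optional[float] = None,
) -> np.ndarray:
    """Group protein positions into protein clusters.

    Proteins sharing a parent localization cluster always stay together —
    they were counted as one kinetic unit.  With ``linking_radius`` set,
    parent groups whose members approach within that distance are merged by
    single linkage; the default (``None``) keeps the parent partition as-is,
    mirroring the convention that one localization cluster is one protein
    cluster candidate.

    Returns an integer group label per protein.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    parents = np.asarray(parent_ids)
    if len(pos) != len(parents):
        raise ValueError("positions and parent_ids must have equal length")
    n = len(pos)
    if n == 0:
        return np.empty(0, dtype=int)
    _, parent_labels = np.unique(parents, return_inverse=True)
    if linking_radius is None or n == 1:
        return parent_labels
    pairs = cKDTree(pos).query_pairs(r=linking_radius, output_type="ndarray")
    rows = np.concatenate([pairs[:, 0], np.arange(n)])
    cols = np.concatenate([pairs[:, 1], parent_labels + n])
    data = np.ones(len(rows), dtype=np.int8)
    graph = coo_matrix(
        (data, (rows, cols)), shape=(n + parent_labels.max() + 1,) * 2
    )
    _, labels = connected_components(graph, directed=False)
    _, out = np.unique(labels[:n], return_inverse=True)
    return out


def classify_cluster(n_proteins: int) -> str:
    """Size class of a protein cluster: small (<6), medium (6-12), large (>12)."""
    if n_proteins < MIN_CLUSTER_SIZE:
        raise ValueError("a protein cluster has at least three members")
    if n_proteins < 6:
        return "small"
    if n_proteins <= 12:
        return "medium"
    return "large"


def equivalent_diameter(points: np.ndarray) -> float:
    """Diameter of the circle with the same area as the convex hull, nm."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return float("nan")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float("nan")
    return float(2.0 * np.sqrt(hull.volume / np.pi))  # 2D: volume is the area


def morphology_index(polygon) -> float:
    """Shape index perimeter^2 / (4 pi area) of a simple closed contour.

    Equals 1 for a circle (in the continuum limit) and grows with
    elongation; dimensionless, hence scale invariant.  Accepts a shapely
    polygon or an (n, 2) vertex array.
    """
    from shapely.geometry import Polygon

    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    if poly.area <= 0:
        raise ValueError("polygon area must be > 0")
    return float(poly.length**2 / (4.0 * np.pi * poly.area))


@dataclass
class ProteinMap:
    """Per-ROI protein positions, parentage and cluster memberships."""

    positions: np.ndarray  # (n, 2) nm
    parent_cluster_ids: np.ndarray  # (n,) localization-cluster id per protein
    group_labels: np.ndarray  # (n,) protein-cluster label
    area_um2: float
    # Localizations of each parent cluster, for hull-based cluster diameters.
    parent_locs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("ROI area must be > 0")
        n = len(self.positions)
        if len(self.parent_cluster_ids) != n or len(self.group_labels) != n:
            raise ValueError("positions, parents and labels must align")

    @property
    def n_proteins(self) -> int:
        return len(self.positions)

    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.group_labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class RoiSummary:
    """The per-ROI statistics of a quantitative protein map."""

    n_proteins: int
    n_clusters: int  # protein clusters with >= 3 members
    protein_density: float  # proteins / um^2
    cluster_density: float  # clusters / um^2
    pct_clustered: Optional[float]  # %, None when the ROI holds no proteins
    n_small: int
    n_medium: int
    n_large: int
    median_equivalent_diameter_nm: float
    median_first_neighbour_nm: float
    area_um2: float

    def to_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "n_clusters": self.n_clusters,
            "protein_density_per_um2": self.protein_density,
            "cluster_density_per_um2": self.cluster_density,
            "pct_clustered": self.pct_clustered,
            "n_small": self.n_small,
            "n_medium": self.n_medium,
            "n_large": self.n_large,
            "median_equivalent_diameter_nm": self.median_equivalent_diameter_nm,
            "median_first_neighbour_nm": self.median_first_neighbour_nm,
            "area_um2": self.area_um2,
        }


def summarize_roi(pmap: ProteinMap, diameter_from: str = "localizations") -> RoiSummary:
    """Compute the per-ROI summary statistics of a protein map.

    Cluster diameters use the convex hull of the member localizations by
    default (``diameter_from="localizations"``), which reflects the physical
    extent of the labelled structure; ``"proteins"`` uses the protein
    positions instead.  First-neighbour distances are Euclidean
    nearest-neighbour distances among all protein positions in the ROI,
    uncorrected for edge effects; the median is reported.
    """
    n = pmap.n_proteins
    if n == 0:
        return RoiSummary(0, 0, 0.0, 0.0, None, 0, 0, 0, float("nan"), float("nan"), pmap.area_um2)

    sizes = pmap.cluster_sizes()
    cluster_labels = [g for g, s in sizes.items() if s >= MIN_CLUSTER_SIZE]
    n_clustered = sum(sizes[g] for g in cluster_labels)
    counts = {"small": 0, "medium": 0, "large": 0}
    diameters = []
    for g in cluster_labels:
        counts[classify_cluster(sizes[g])] += 1
        members = np.flatnonzero(pmap.group_labels == g)
        if diameter_from == "proteins":
            pts = pmap.positions[members]
        else:
            parents = np.unique(pmap.parent_cluster_ids[members])
            locs = [pmap.parent_locs[p] for p in parents if p in pmap.parent_locs]
            pts = np.concatenate(locs) if locs else pmap.positions[members]
        diameters.append(equivalent_diameter(pts))

    if n >= 2:
        dists, _ = cKDTree(pmap.positions).query(pmap.positions, k=2)
        median_nn = float(np.median(dists[:, 1]))
    else:
        median_nn = float("nan")

    return RoiSummary(
        n_proteins=n,
        n_clusters=len(cluster_labels),
        protein_density=n / pmap.area_um2,
        cluster_density=len(cluster_labels) / pmap.area_um2,
        pct_clustered=100.0 * n_clustered / n,
        n_small=counts["small"],
        n_medium=counts["medium"],
        n_large=counts["large"],
        median_equivalent_diameter_nm=float(np.median(diameters)) if diameters else float("nan"),
        median_first_neighbour_nm=median_nn,
        area_um2=pmap.area_um2,
    )
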