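"""Cluster spots on an embedding into spatial clusters and name regions.

Clustering follows the shared-nearest-neighbor (SNN) + Louvain recipe used
for spot segmentation: a kNN graph in PC space, Jaccard-weighted shared
neighborhoods pruned below 1/15, and Louvain modularity optimization with a
resolution parameter (0.15 by default, the granularity at which spot
clusters match anatomical structure). Cluster labels are relabeled by
descending size. Region naming is explicit configuration — a cluster to
region-name map — replacing visual atlas comparison; a majority-vote helper
derives that map from ground truth in synthetic studies.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "RegionAssignment",
    "snn_graph",
    "cluster_snn_louvain",
    "label_regions",
    "majority_vote_names",
]

UNASSIGNED = "unassigned"


@dataclass
class RegionAssignment:
    cluster_id: np.ndarray  # per spot
    region_name_map: dict[int, str]  # cluster -> region (many-to-one allowed)
    resolution: float
    n_clusters: int

    @property
    def region(self) -> np.ndarray:
        return np.array(
            [self.region_name_map.get(int(c), UNASSIGNED) for c in self.cluster_id]
        )

    def to_frame(self, obs: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.cluster_id, "region": self.region})
        if obs is not None:
            df.index = obs.index
            df = pd.concat([obs[["slide_id", "barcode"]], df], axis=1)
        return df


def snn_graph(coords: np.ndarray, k_nn: int = 20, prune: float = 1 / 15) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph (self included in kNN)."""
    n = coords.shape[0]
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be smaller than n_spots={n}")
    nn = NearestNeighbors(n_neighbors=k_nn).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k_nn)
    A = sp.csr_matrix(
        (np.ones(n * k_nn), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()  # |N(i) & N(j)|
    jac = shared.data / (2.0 * k_nn - shared.data)
    keep = jac >= prune
    W = sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def cluster_snn_louvain(
    embedding,
    k_nn: int = 20,
    resolution: float = 0.15,
    seed: int = 0,
    prune: float = 1 / 15,
) -> np.ndarray:
    """Louvain communities of the SNN graph, relabeled by descending size.

    ``embedding`` is either an :class:`~stquant.prep_integrate.Embedding`
    or a raw (spot, dim) coordinate array. Louvain is seeded for
    reproducibility.
    """
    coords = getattr(embedding, "coordinates", embedding)
    W = snn_graph(np.asarray(coords), k_nn=k_nn, prune=prune)
    Wu = sp.triu(W.maximum(W.T), k=1).tocoo()
    g = igraph.Graph(
        n=W.shape[0],
        edges=list(zip(Wu.row.tolist(), Wu.col.tolist())),
        edge_attrs={"weight": Wu.data.tolist()},
    )
    random.seed(seed)
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # Relabel by descending cluster size; ties by first appearance.
    sizes = pd.Series(labels).value_counts(sort=False)
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def label_regions(
    labels: np.ndarray,
    name_map: dict[int, str],
    resolution: float = 0.15,
    expected: list[str] | None = None,
) -> RegionAssignment:
    """Attach region names to clusters; unmapped clusters become 'unassigned'."""
    observed = set(int(c) for c in np.unique(labels))
    for c in name_map:
        if int(c) not in observed:
            warnings.warn(f"name map references absent cluster {c}")
    unmapped = observed - {int(c) for c in name_map}
    if unmapped:
        warnings.warn(f"clusters without region name: {sorted(unmapped)}")
    full_map = {c: name_map.get(c, UNASSIGNED) for c in observed}
    if expected is not None:
        missing = set(expected) - set(full_map.values())
        if missing:
            warnings.warn(f"expected regions not assigned: {sorted(missing)}")
    return RegionAssignment(
        cluster_id=np.asarray(labels),
        region_name_map=full_map,
        resolution=resolution,
        n_clusters=len(observed),
    )


def majority_vote_names(labels: np.ndarray, truth_regions) -> dict[int, str]:
    """Name each cluster by the most common ground-truth region among its spots."""
    truth = np.asarray(truth_regions)
    out: dict[int, str] = {}
    for c in np.unique(labels):
        vals, counts = np.unique(truth[labels == c], return_counts=True)
        out[int(c)] = str(vals[np.argmax(counts)])
    return out
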