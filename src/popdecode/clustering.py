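"""Semi-supervised identity grouping of crop-cluster embeddings.

Crop clusters (tracked image patches of one person within one cut,
represented by per-crop face-embedding vectors) are merged into
identities in three moves: (1) k-means over cluster feature vectors
with a distortion gate yields pure "supernodes"; (2) remaining
candidate crop clusters are absorbed by their nearest supernode when
close enough, iterating while supernodes keep growing; (3) a pruned
centroid graph's connected components give the final identities. Frame
spans provide a hard negative constraint: two clusters on screen at the
same time cannot be the same person.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .synthetic import CropCluster, CropClusterSet

__all__ = ["ClusterFeature", "Supernode", "ClusteringConfig",
           "compute_cluster_features", "cluster_distance", "form_supernodes",
           "absorb_candidates", "finetune_graph", "purity_completeness",
           "run_stage2", "default_config", "Stage2Result"]

FACELESS_DROP = 0.8     # drop clusters losing over 80% of crops to no-face


@dataclass
class ClusterFeature:
    cluster_id: int
    feature: np.ndarray
    n_retained: int


@dataclass
class Supernode:
    members: list[int]             # crop-cluster ids
    distortion: float

    def centroid(self, features: dict[int, np.ndarray]) -> np.ndarray:
        return np.mean([features[m] for m in self.members], axis=0)


@dataclass
class ClusteringConfig:
    k: int                          # k-means super-cluster count
    n_neighbors: int = 5            # K for the cluster distance
    distortion_threshold: float = 1.0
    assignment_threshold: float = 1.0
    growth_threshold: float = 0.1   # fractional crop growth to keep iterating
    prune_threshold: float = 1.0
    seed: int = 0
    distance_mode: str = "pooled"   # or "nearest_k"

    def __post_init__(self):
        for name in ("distortion_threshold", "assignment_threshold",
                     "growth_threshold", "prune_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


def compute_cluster_features(crops: CropClusterSet
                             ) -> tuple[list[ClusterFeature], list[int]]:
    """Mean face-embedding per cluster over crops with faces.

    Clusters losing more than 80% of their crops for lack of facial
    features are dropped; returns (features, dropped cluster ids)."""
    if not crops.clusters:
        raise ValueError("empty crop-cluster set")
    features, dropped = [], []
    for cl in crops.clusters:
        kept = cl.has_face
        if 1.0 - kept.mean() > FACELESS_DROP:
            dropped.append(cl.cluster_id)
            continue
        features.append(ClusterFeature(cl.cluster_id,
                                       cl.embeddings[kept].mean(axis=0),
                                       int(kept.sum())))
    return features, dropped


def _face_embeddings(cl: CropCluster) -> np.ndarray:
    emb = cl.embeddings[cl.has_face]
    return emb if len(emb) else cl.embeddings


def cluster_distance(a: np.ndarray, b: np.ndarray, n_neighbors: int = 5,
                     mode: str = "pooled") -> float:
    """Distance from crop set A to crop set B (asymmetric).

    ``pooled``: per member of A, its ``n_neighbors`` nearest Euclidean
    distances to members of B are pooled; the median of the pool is
    returned. ``nearest_k``: the median of the ``n_neighbors`` smallest
    per-member nearest distances.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty crop set")
    k = n_neighbors
    if k > len(b):
        warnings.warn("K exceeds |B|; clipping")
        k = len(b)
    d = np.sqrt(np.maximum(
        (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :]
        - 2.0 * a @ b.T, 0.0))
    if mode == "pooled":
        pool = np.sort(d, axis=1)[:, :k].ravel()
        return float(np.median(pool))
    if mode == "nearest_k":
        nearest = np.sort(d.min(axis=1))[:min(k, len(a))]
        return float(np.median(nearest))
    raise ValueError(f"unknown mode {mode!r}")


def form_supernodes(features: list[ClusterFeature], config: ClusteringConfig
                    ) -> tuple[list[Supernode], list[int]]:
    """k-means over cluster features; super-clusters whose distortion
    (mean squared distance to centroid) is below the threshold become
    supernodes, the rest dissolve into candidate crop clusters."""
    if config.k > len(features):
        raise ValueError("k exceeds the number of cluster features")
    x = np.stack([f.feature for f in features])
    km = KMeans(n_clusters=config.k, n_init=4, random_state=config.seed)
    assign = km.fit_predict(x)
    supernodes, candidates = [], []
    for g in range(config.k):
        sel = np.flatnonzero(assign == g)
        if len(sel) == 0:
            continue
        dists2 = ((x[sel] - km.cluster_centers_[g]) ** 2).sum(axis=1)
        distortion = float(dists2.mean())
        ids = [features[i].cluster_id for i in sel]
        if distortion < config.distortion_threshold:
            supernodes.append(Supernode(members=ids, distortion=distortion))
        else:
            candidates.extend(ids)
    return supernodes, candidates


def absorb_candidates(supernodes: list[Supernode], candidates: list[int],
                      crops: CropClusterSet, config: ClusteringConfig
                      ) -> tuple[list[Supernode], list[int], int]:
    """KNN absorption loop.

    In the first pass a candidate's distance to a supernode is the
    minimum cluster distance to any member cluster; afterwards each
    supernode is treated as a single (pooled) crop cluster. A candidate
    is absorbed by the nearest supernode if that distance is below the
    assignment threshold. Iterations continue while some supernode grows
    by more than the growth threshold (fraction of its crop count).
    Returns (supernodes, unabsorbed candidates, n_iterations).
    """
    if not supernodes:
        raise ValueError("need at least one supernode")
    by_id = {c.cluster_id: c for c in crops.clusters}
    candidates = list(candidates)
    iteration = 0
    first_pass = True
    while candidates:
        iteration += 1
        pooled = {}
        for si, sn in enumerate(supernodes):
            pooled[si] = np.concatenate(
                [_face_embeddings(by_id[m]) for m in sn.members])
        sizes_before = {si: len(pooled[si]) for si in pooled}
        absorbed_by: dict[int, list[int]] = {si: [] for si in pooled}
        remaining = []
        for cid in candidates:
            emb = _face_embeddings(by_id[cid])
            dists = []
            for si, sn in enumerate(supernodes):
                if first_pass:
                    d = min(cluster_distance(
                        emb, _face_embeddings(by_id[m]),
                        config.n_neighbors, config.distance_mode)
                        for m in sn.members)
                else:
                    d = cluster_distance(emb, pooled[si],
                                         config.n_neighbors,
                                         config.distance_mode)
                dists.append(d)
            best = int(np.argmin(dists))
            if dists[best] < config.assignment_threshold:
                absorbed_by[best].append(cid)
            else:
                remaining.append(cid)
        grew = False
        for si, new_ids in absorbed_by.items():
            if not new_ids:
                continue
            supernodes[si].members.extend(new_ids)
            added = sum(len(_face_embeddings(by_id[c])) for c in new_ids)
            if added / sizes_before[si] > config.growth_threshold:
                grew = True
        candidates = remaining
        first_pass = False
        if not grew:
            break
    return supernodes, candidates, iteration


def finetune_graph(node_ids: list[int], centroids: np.ndarray,
                   frame_spans: list[list[tuple[float, float]]],
                   prune_threshold: float) -> list[list[int]]:
    """Connected components of the pruned complete centroid graph.

    Edges with Euclidean weight above the pruning threshold, or between
    nodes whose frame spans overlap (two people on screen at once cannot
    be the same character), are removed.
    """
    n = len(node_ids)
    if n == 0:
        return []
    d = np.sqrt(np.maximum(
        (centroids ** 2).sum(1)[:, None] + (centroids ** 2).sum(1)[None, :]
        - 2.0 * centroids @ centroids.T, 0.0))
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > prune_threshold:
                continue
            overlap = any(s1 < e2 and s2 < e1
                          for (s1, e1) in frame_spans[i]
                          for (s2, e2) in frame_spans[j])
            if not overlap:
                adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return [[node_ids[i] for i in np.flatnonzero(labels == g)]
            for g in range(n_comp)]


def purity_completeness(components: list[list[int]],
                        crops: CropClusterSet) -> tuple[float, float]:
    """Component purity and planted-class completeness, weighted by
    cluster counts."""
    identity = {c.cluster_id: c.identity for c in crops.clusters}
    total = sum(len(comp) for comp in components)
    purity = 0.0
    class_best: dict[int, int] = {}
    class_total: dict[int, int] = {}
    for comp in components:
        labs = [identity[c] for c in comp]
        counts: dict[int, int] = {}
        for lab in labs:
            counts[lab] = counts.get(lab, 0) + 1
        purity += max(counts.values())
        for lab, cnt in counts.items():
            class_best[lab] = max(class_best.get(lab, 0), cnt)
    for cid, lab in identity.items():
        if any(cid in comp for comp in components):
            class_total[lab] = class_total.get(lab, 0) + 1
    purity /= total
    completeness = float(np.mean(
        [class_best[lab] / class_total[lab] for lab in class_total]))
    return float(purity), completeness


@dataclass
class Stage2Result:
    components: list[list[int]]     # component -> crop-cluster ids
    supernodes: list[Supernode]
    unabsorbed: list[int]
    dropped: list[int]
    n_iterations: int
    purity: float | None = None
    completeness: float | None = None


def default_config(crops: CropClusterSet, expected_identities: int,
                   seed: int = 0) -> ClusteringConfig:
    """Thresholds calibrated from the data's own distance scale.

    The median nearest-neighbour feature distance d_nn estimates the
    within-identity scale; the distortion gate, assignment radius and
    graph-pruning radius are set as fixed multiples of it, and k is
    three times the expected identity count.
    """
    features, _ = compute_cluster_features(crops)
    x = np.stack([f.feature for f in features])
    d = np.sqrt(np.maximum(
        (x * x).sum(1)[:, None] + (x * x).sum(1)[None, :] - 2 * x @ x.T, 0))
    np.fill_diagonal(d, np.inf)
    nn_idx = d.argmin(axis=1)
    d_nn = float(np.median(d.min(axis=1)))
    # the assignment radius lives on the crop-distance scale, which is
    # dominated by per-crop noise and much larger than feature distances
    by_id = {c.cluster_id: c for c in crops.clusters}
    crop_dists = []
    for fi, f in enumerate(features):
        a = _face_embeddings(by_id[f.cluster_id])
        b = _face_embeddings(by_id[features[nn_idx[fi]].cluster_id])
        crop_dists.append(cluster_distance(a, b, 5))
    d_crop = float(np.median(crop_dists))
    return ClusteringConfig(
        k=min(3 * expected_identities, len(features)),
        n_neighbors=5,
        distortion_threshold=(1.2 * d_nn) ** 2,
        assignment_threshold=1.5 * d_crop,
        growth_threshold=0.1,
        prune_threshold=6.0 * d_nn,
        seed=seed)


def run_stage2(crops: CropClusterSet, config: ClusteringConfig
               ) -> Stage2Result:
    """Full Stage-2 loop: features, supernode formation, candidate
    absorption, graph fine-tuning; purity/completeness when planted
    identities are available."""
    features, dropped = compute_cluster_features(crops)
    feat_by_id = {f.cluster_id: f.feature for f in features}
    supernodes, candidates = form_supernodes(features, config)
    if supernodes:
        supernodes, candidates, n_iter = absorb_candidates(
            supernodes, candidates, crops, config)
    else:
        n_iter = 0
    by_id = {c.cluster_id: c for c in crops.clusters}
    node_ids, centroids, spans, node_members = [], [], [], []
    for si, sn in enumerate(supernodes):
        node_ids.append(-(si + 1))
        centroids.append(sn.centroid(feat_by_id))
        spans.append([by_id[m].frame_span for m in sn.members])
        node_members.append(list(sn.members))
    for cid in candidates:
        node_ids.append(cid)
        centroids.append(feat_by_id[cid])
        spans.append([by_id[cid].frame_span])
        node_members.append([cid])
    comps_nodes = finetune_graph(node_ids, np.stack(centroids), spans,
                                 config.prune_threshold)
    id_to_members = dict(zip(node_ids, node_members))
    components = [sorted(sum((id_to_members[nid] for nid in comp), []))
                  for comp in comps_nodes]
    result = Stage2Result(components=components, supernodes=supernodes,
                          unabsorbed=candidates, dropped=dropped,
                          n_iterations=n_iter)
    if all(c.identity is not None for c in crops.clusters):
        result.purity, result.completeness = purity_completeness(
            components, crops)
    return result
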