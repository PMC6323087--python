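"""Unsupervised molecular-image segmentation by divisive k-means.

Pixels are split recursively by 2-means on locally filtered, log-transformed
component abundances.  A node stops splitting when it is smaller than a
fraction of the image or when the distribution of member-to-centroid
distances is unimodal (dip test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._dip import dip_pvalue
from .io_core import FeatureTable, ValidationError

STOP_TOO_SMALL = "too_small"
STOP_UNIMODAL = "unimodal"
STOP_SPLIT = "split"

#: caps for the dip test: pixels entering the pairwise-distance matrix and
#: distances entering the statistic (it stabilizes long before; keeps deep
#: recursions fast)
_DIP_MAX_PIXELS = 300
_DIP_MAX_N = 2000
#: distances are computed in the span of this many leading PCs
_DIP_MAX_DIMS = 3


@dataclass
class SplitNode:
    node_id: int
    pixels: np.ndarray
    stop_reason: str
    children: tuple[int, int] | None = None


@dataclass
class SegmentationResult:
    cluster_id: np.ndarray  # per-pixel leaf label, 0..n_clusters-1
    split_tree: list[SplitNode] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) + 1

    def summary(self) -> dict:
        return summarize_segments(self)


def unimodality_check(
    pixels: np.ndarray, alpha: float = 0.05, seed: int = 0
) -> bool:
    """True (stop splitting) when the intra-cluster distance distribution
    looks unimodal.

    Pairwise Euclidean distances between member pixels (subsampled for
    speed, computed in the top principal-component subspace so that noise
    dimensions do not blur the modes) are submitted to a dip test; failing
    to reject unimodality at ``alpha`` returns True.  Pairwise distances
    split into within/between modes when two sub-populations exist, which
    member-to-centroid distances miss when the sub-populations are
    symmetric about the mean.
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    n = pixels.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 pixels for a unimodality check")
    rng = np.random.default_rng(seed)
    if n > _DIP_MAX_PIXELS:
        pixels = pixels[rng.choice(n, _DIP_MAX_PIXELS, replace=False)]
        n = _DIP_MAX_PIXELS
    centred = pixels - pixels.mean(axis=0)
    if centred.shape[1] > _DIP_MAX_DIMS:
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        pixels = centred @ vt[:_DIP_MAX_DIMS].T
    diff = pixels[:, None, :] - pixels[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))[np.triu_indices(n, 1)]
    if np.allclose(dist, dist[0]):
        return True
    if dist.size > _DIP_MAX_N:
        dist = rng.choice(dist, size=_DIP_MAX_N, replace=False)
    return dip_pvalue(dist) > alpha


def _node_features(x: np.ndarray) -> np.ndarray:
    """Per-node feature filtering: keep components whose within-node CV is
    at or above the node median CV."""
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = cv >= np.median(cv)
    if not np.any(keep):
        keep = np.ones(x.shape[1], dtype=bool)
    return x[:, keep]


def divik_segment(
    table: FeatureTable,
    min_cluster_frac: float = 0.01,
    seed: int = 0,
    alpha: float = 0.05,
    max_depth: int = 30,
) -> SegmentationResult:
    """Recursive divisive 2-means over the feature table's pixels."""
    if table.n_components == 0 or table.n_pixels == 0:
        raise ValidationError("empty feature table")
    if not 0.0 < min_cluster_frac < 1.0:
        raise ValidationError("min_cluster_frac must be in (0, 1)")
    n_total = table.n_pixels
    if n_total < 2:
        raise ValidationError("need at least 2 pixels")
    data = np.log1p(np.clip(table.abundances.T, 0.0, None))  # pixels x comps
    min_size = min_cluster_frac * n_total

    tree: list[SplitNode] = []
    cluster_id = np.full(n_total, -1, dtype=int)
    leaves: list[np.ndarray] = []

    def recurse(pixels: np.ndarray, depth: int, node_seed: int) -> int:
        node_id = len(tree)
        node = SplitNode(node_id, pixels, STOP_SPLIT)
        tree.append(node)
        if pixels.size < min_size or pixels.size < 4 or depth >= max_depth:
            node.stop_reason = STOP_TOO_SMALL
            leaves.append(pixels)
            return node_id
        x = _node_features(data[pixels])
        if unimodality_check(x, alpha=alpha, seed=node_seed):
            node.stop_reason = STOP_UNIMODAL
            leaves.append(pixels)
            return node_id
        km = KMeans(n_clusters=2, n_init=10, random_state=node_seed % (2**31))
        lab = km.fit_predict(x)
        if np.all(lab == lab[0]):  # degenerate split
            node.stop_reason = STOP_UNIMODAL
            leaves.append(pixels)
            return node_id
        left = recurse(pixels[lab == 0], depth + 1, node_seed * 2 + 1)
        right = recurse(pixels[lab == 1], depth + 1, node_seed * 2 + 2)
        node.children = (left, right)
        return node_id

    recurse(np.arange(n_total), 0, seed + 1)
    for cid, pixels in enumerate(leaves):
        cluster_id[pixels] = cid
    return SegmentationResult(cluster_id, tree)


def summarize_segments(result: SegmentationResult) -> dict:
    """Cluster count plus average / largest cluster size as % of pixels."""
    n = result.cluster_id.size
    if n == 0:
        raise ValidationError("empty segmentation")
    sizes = np.bincount(result.cluster_id)
    k = sizes.size
    return {
        "n_clusters": int(k),
        "avg_size_pct": round(100.0 / k, 2),
        "largest_size_pct": round(100.0 * sizes.max() / n, 2),
    }
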