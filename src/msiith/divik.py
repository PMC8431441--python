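"""Divisive iterated k-means segmentation with per-node feature selection.

The pooled pixel-by-component matrix is split recursively: at each node a
region-driven feature filter retains the informative components, a Dunn-index
scan over k picks the best k-means partition, and a GAP-statistic comparison
against uniform reference data decides whether the split is kept.  Clusters
that stop splitting persist unchanged at deeper levels, so per-level flat
label vectors are always defined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .components import FeatureMatrix
from .datatypes import DivikParams

logger = logging.getLogger("msiith")

__all__ = [
    "SegmentationNode",
    "SegmentationTree",
    "LevelLabels",
    "filter_features",
    "choose_k",
    "should_split",
    "divik",
    "labels_at_level",
]


@dataclass
class SegmentationNode:
    node_id: str  # path label, e.g. "2.1.3"; "" is the root
    depth: int
    members: np.ndarray  # pixel row indices into the pooled feature matrix
    selected_features: Optional[np.ndarray] = None
    children: List["SegmentationNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LevelLabels:
    level: int
    labels: np.ndarray  # per-pixel path label truncated to `level` segments
    k: int


@dataclass
class SegmentationTree:
    root: SegmentationNode
    n_pixels: int
    max_depth: int
    pixel_paths: np.ndarray  # per-pixel full path label (deepest leaf)

    def labels_at_level(self, level: int) -> LevelLabels:
        return labels_at_level(self, level)

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def summary(self) -> dict:
        def walk(node):
            return {
                "node_id": node.node_id or "root",
                "depth": node.depth,
                "n_pixels": int(node.members.size),
                "n_selected_features": (
                    None if node.selected_features is None else int(node.selected_features.size)
                ),
                "children": [walk(c) for c in node.children],
            }

        return {
            "n_pixels": self.n_pixels,
            "max_depth": self.max_depth,
            "tree": walk(self.root),
        }

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


# --------------------------------------------------------------------------
# Feature filtering


def _top_mixture_selection(
    values: np.ndarray, min_keep_frac: float = 0.01, min_keep: int = 3
) -> np.ndarray:
    """Fit a 1-3 component mixture to per-feature log2 statistics and keep
    features assigned to the highest-mean component(s), walking down until at
    least ``min_keep_frac`` of features (and never fewer than ``min_keep``,
    so downstream correlation distances stay meaningful) survive."""
    x = values[:, None]
    best, best_bic = None, np.inf
    for k in (1, 2, 3):
        if k >= len(values):
            break
        gm = GaussianMixture(n_components=k, random_state=0, n_init=2, reg_covar=1e-9)
        gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    if best is None or best.n_components == 1:
        return np.arange(len(values))
    assign = best.predict(x)
    order = np.argsort(best.means_.ravel())[::-1]  # high mean first
    selected = np.zeros(len(values), dtype=bool)
    needed = max(min(min_keep, len(values)), int(np.ceil(min_keep_frac * len(values))))
    for comp in order:
        selected |= assign == comp
        if selected.sum() >= needed:
            break
    return np.flatnonzero(selected)


def filter_features(sub_matrix: np.ndarray, mode: str = "variance_gmm") -> np.ndarray:
    """Region-driven feature selection on a node's pixel-by-feature block.

    ``variance_gmm`` keeps features in the top mode(s) of the log2 variance
    distribution; ``amplitude_gmm`` does the same on log2 mean abundance;
    ``none`` keeps everything.  If all features are constant, filtering is
    impossible and the full set is returned with a warning.
    """
    n_features = sub_matrix.shape[1]
    if mode == "none":
        return np.arange(n_features)
    if mode == "variance_gmm":
        stat = sub_matrix.var(axis=0)
    elif mode == "amplitude_gmm":
        stat = sub_matrix.mean(axis=0)
    else:
        raise ValueError(f"unknown feature filter {mode!r}")
    if np.all(stat <= 0) or np.allclose(stat, stat[0]):
        logger.warning("all features constant at this node; filtering impossible")
        return np.arange(n_features)
    log_stat = np.log2(np.maximum(stat, np.finfo(float).tiny))
    return _top_mixture_selection(log_stat)


# --------------------------------------------------------------------------
# Distance handling: correlation distance == scaled Euclidean on row-z-scored
# vectors, so a single vanilla k-means backend serves both metrics.


def _prep_rows(X: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return np.asarray(X, dtype=np.float64)
    if distance != "correlation":
        raise ValueError(f"unknown distance {distance!r}")
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=1, keepdims=True)
    Z = X - mu
    norm = np.linalg.norm(Z, axis=1, keepdims=True)
    zero = norm.ravel() == 0
    if zero.any():
        logger.warning("%d constant pixel vectors mapped to the origin", int(zero.sum()))
    norm[norm == 0] = 1.0
    return Z / norm


def _dunn_index(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray, rng: np.random.Generator,
    diameter_cap: int = 1500,
) -> float:
    """min inter-centroid distance / max intra-cluster diameter; clusters
    larger than the cap contribute a seeded-subsample diameter estimate."""
    k = centroids.shape[0]
    inter = np.inf
    for i in range(k):
        d = np.linalg.norm(centroids[i + 1 :] - centroids[i], axis=1)
        if d.size:
            inter = min(inter, d.min())
    diam = 0.0
    for c in range(k):
        pts = X[labels == c]
        if pts.shape[0] < 2:
            continue
        if pts.shape[0] > diameter_cap:
            idx = rng.choice(pts.shape[0], size=diameter_cap, replace=False)
            pts = pts[idx]
        g = pts @ pts.T
        sq = np.diag(g)
        d2 = sq[:, None] + sq[None, :] - 2 * g
        diam = max(diam, float(np.sqrt(max(d2.max(), 0.0))))
    if diam == 0.0:
        return np.inf
    return inter / diam


def choose_k(
    sub_matrix: np.ndarray,
    params: DivikParams,
    seed: Optional[int] = None,
) -> Optional[Tuple[int, np.ndarray, np.ndarray]]:
    """Scan k = 2..k_max with seeded k-means and return the Dunn-optimal
    ``(k, labels, centroids)`` in the prepped space, or None when the rows
    carry no structure (all identical)."""
    seed = params.seed if seed is None else seed
    X = _prep_rows(sub_matrix, params.distance)
    if np.allclose(X, X[0]):
        return None
    rng = np.random.default_rng(seed)
    best = None
    best_dunn = -np.inf
    k_hi = min(params.k_max, X.shape[0] - 1)
    for k in range(2, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=params.n_init, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < k:
            continue
        dunn = _dunn_index(X, labels, km.cluster_centers_, rng)
        if dunn > best_dunn + 1e-12:  # ties break toward smaller k
            best_dunn = dunn
            best = (k, labels, km.cluster_centers_)
    return best


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return max(w, np.finfo(float).tiny)


def should_split(
    sub_matrix: np.ndarray,
    candidate: Tuple[int, np.ndarray, np.ndarray],
    params: DivikParams,
    seed: Optional[int] = None,
) -> bool:
    """GAP-statistic split decision.

    Accept the candidate k-way split iff ``gap(k) - s(k) >= gap(1)``
    (Tibshirani's one-standard-error placement, comparing the split against
    the unsplit node), with the gap estimated from B seeded reference
    datasets drawn uniformly in the feature-wise bounding box of the node's
    (prepped) data.
    """
    seed = params.seed if seed is None else seed
    k, labels, _ = candidate
    X = _prep_rows(sub_matrix, params.distance)
    rng = np.random.default_rng(seed)
    log_wk = np.log(_within_dispersion(X, labels))
    log_w1 = np.log(_within_dispersion(X, np.zeros(X.shape[0], dtype=int)))

    # references live in the raw data's bounding box and get the same
    # distance prep as the data, so their geometry is comparable
    lo = np.asarray(sub_matrix).min(axis=0)
    hi = np.asarray(sub_matrix).max(axis=0)
    ref_k = np.empty(params.gap_reference_count)
    ref_1 = np.empty(params.gap_reference_count)
    for b in range(params.gap_reference_count):
        R = _prep_rows(rng.uniform(lo, hi, size=X.shape), params.distance)
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + b)
        rl = km.fit_predict(R)
        ref_k[b] = np.log(_within_dispersion(R, rl))
        ref_1[b] = np.log(_within_dispersion(R, np.zeros(R.shape[0], dtype=int)))
    gap_k = ref_k.mean() - log_wk
    gap_1 = ref_1.mean() - log_w1
    s_k = ref_k.std(ddof=0) * np.sqrt(1.0 + 1.0 / params.gap_reference_count)
    return bool(gap_k - s_k >= gap_1)


# --------------------------------------------------------------------------


def divik(features: FeatureMatrix, params: Optional[DivikParams] = None) -> SegmentationTree:
    """Recursive filter -> choose_k -> should_split segmentation of the
    pooled feature matrix; deterministic for a given params.seed."""
    params = params or DivikParams()
    values = features.values
    if values.size == 0:
        raise ValueError("empty feature matrix")
    n = values.shape[0]

    def node_seed(node_id: str) -> int:
        # deterministic per-node stream derived from the path label
        h = np.random.SeedSequence([params.seed] + [int(s) for s in node_id.split(".") if s])
        return int(h.generate_state(1)[0])

    def recurse(members: np.ndarray, node_id: str, depth: int) -> SegmentationNode:
        node = SegmentationNode(node_id=node_id, depth=depth, members=members)
        if depth >= params.max_depth:
            return node
        if members.size < params.min_split_size:
            return node
        block = values[members]
        selected = filter_features(block, params.feature_filter)
        node.selected_features = selected
        sub = block[:, selected]
        seed = node_seed(node_id)
        candidate = choose_k(sub, params, seed=seed)
        if candidate is None:
            return node
        if not should_split(sub, candidate, params, seed=seed):
            return node
        k, labels, _ = candidate
        for c in range(k):
            child_id = f"{node_id}.{c + 1}" if node_id else str(c + 1)
            child = recurse(members[labels == c], child_id, depth + 1)
            node.children.append(child)
        return node

    root = recurse(np.arange(n), "", 0)
    paths = np.empty(n, dtype=object)
    for node in _iter_leaves(root):
        label = node.node_id if node.node_id else "1"
        paths[node.members] = label
    return SegmentationTree(root=root, n_pixels=n, max_depth=params.max_depth, pixel_paths=paths)


def _iter_leaves(node: SegmentationNode):
    if node.is_leaf:
        yield node
    else:
        for c in node.children:
            yield from _iter_leaves(c)


def labels_at_level(tree: SegmentationTree, level: int) -> LevelLabels:
    """Flatten the tree at a depth: per-pixel label = path truncated to
    ``level`` segments (shorter paths persist unchanged)."""
    if not (1 <= level <= tree.max_depth):
        raise ValueError(f"level must be in 1..{tree.max_depth}, got {level}")
    truncated = np.array(
        [".".join(p.split(".")[:level]) for p in tree.pixel_paths], dtype=object
    )
    return LevelLabels(level=level, labels=truncated, k=len(set(truncated)))
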