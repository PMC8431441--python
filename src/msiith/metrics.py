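"""Per-ROI heterogeneity quantification: pairwise spectral similarity with
its cumulative distribution, per-level cluster counts, and Simpson's
diversity index."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .components import FeatureMatrix
from .datatypes import CohortDataset, MetricsConfig
from .divik import SegmentationTree

logger = logging.getLogger("msiith")

__all__ = [
    "SimilaritySummary",
    "HeterogeneityProfile",
    "pairwise_similarity",
    "simpson_index",
    "roi_profiles",
    "roi_size_cluster_correlation",
]


@dataclass
class SimilaritySummary:
    roi_id: str
    n_pairs_evaluated: int
    median_similarity: float
    ecdf: np.ndarray  # (n, 2): sorted similarity, cumulative probability


@dataclass
class HeterogeneityProfile:
    roi_id: str
    n_pixels: int
    cluster_counts: Dict[int, int]  # level -> K within this ROI
    simpson: Dict[int, float]  # level -> D
    similarity_median: Optional[float] = None


# --------------------------------------------------------------------------


def _pair_similarities(rows: np.ndarray, i: np.ndarray, j: np.ndarray, measure: str) -> np.ndarray:
    a = rows[i]
    b = rows[j]
    if measure == "pearson":
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
    elif measure != "cosine":
        raise ValueError(f"unknown similarity measure {measure!r}")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    zero = denom == 0
    if zero.any():
        logger.warning("%d pairs involve a zero-variance pixel; similarity set to 0", int(zero.sum()))
    denom[zero] = 1.0
    sim = np.einsum("ij,ij->i", a, b) / denom
    sim[zero] = 0.0
    return np.clip(sim, -1.0, 1.0)


def pairwise_similarity(
    roi_features: np.ndarray,
    roi_id: str = "",
    max_pairs: int = 100_000,
    seed: int = 0,
    measure: str = "pearson",
) -> SimilaritySummary:
    """Similarity (Pearson correlation by default) over pixel pairs.

    All unordered pairs are evaluated when their count fits in ``max_pairs``;
    otherwise a seeded uniform subsample of ``max_pairs`` pairs is scored.
    """
    rows = np.asarray(roi_features, dtype=np.float64)
    P = rows.shape[0]
    if P < 2:
        raise ValueError("need at least 2 pixels for pairwise similarity")
    n_pairs = P * (P - 1) // 2
    if n_pairs <= max_pairs:
        iu, ju = np.triu_indices(P, k=1)
    else:
        rng = np.random.default_rng(seed)
        iu = rng.integers(0, P, size=int(max_pairs * 1.1) + 8)
        ju = rng.integers(0, P, size=iu.size)
        ok = iu != ju
        iu, ju = iu[ok][:max_pairs], ju[ok][:max_pairs]
    sims = _pair_similarities(rows, iu, ju, measure)
    order = np.sort(sims)
    ecdf = np.column_stack([order, np.arange(1, order.size + 1) / order.size])
    return SimilaritySummary(
        roi_id=roi_id,
        n_pairs_evaluated=int(sims.size),
        median_similarity=float(np.median(sims)),
        ecdf=ecdf,
    )


def simpson_index(labels: Sequence, estimator: str = "distinct_pairs") -> float:
    """Probability that two randomly selected pixels carry different labels.

    ``distinct_pairs`` samples without replacement:
    ``D = 1 - sum n_i (n_i - 1) / (N (N - 1))``; ``plug_in`` uses
    ``D = 1 - sum (n_i / N)^2``.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    n = labels.size
    if estimator == "distinct_pairs":
        if n < 2:
            raise ValueError("distinct_pairs estimator needs >= 2 pixels")
        return float(1.0 - (counts * (counts - 1.0)).sum() / (n * (n - 1.0)))
    if estimator == "plug_in":
        return float(1.0 - ((counts / n) ** 2).sum())
    raise ValueError(f"unknown Simpson estimator {estimator!r}")


def roi_profiles(
    cohort: CohortDataset,
    tree: SegmentationTree,
    features: FeatureMatrix,
    config: Optional[MetricsConfig] = None,
) -> List[HeterogeneityProfile]:
    """Per-ROI cluster counts and Simpson indices at every level, plus the
    median pairwise similarity."""
    cfg = config or MetricsConfig()
    profiles = []
    levels = {lv: tree.labels_at_level(lv) for lv in range(1, tree.max_depth + 1)}
    for roi in cohort.rois:
        rows = features.rows_of(roi.roi_id)
        if rows.size == 0:
            logger.warning("ROI %s has no unflagged pixels; profile omitted", roi.roi_id)
            continue
        counts = {}
        simpson = {}
        for lv, lab in levels.items():
            roi_labels = lab.labels[rows]
            counts[lv] = len(set(roi_labels))
            simpson[lv] = (
                simpson_index(roi_labels, cfg.simpson_estimator) if rows.size >= 2 else 0.0
            )
        sim_median = None
        if rows.size >= 2:
            sim = pairwise_similarity(
                features.values[rows],
                roi_id=roi.roi_id,
                max_pairs=cfg.max_pairs,
                measure=cfg.similarity,
            )
            sim_median = sim.median_similarity
        profiles.append(
            HeterogeneityProfile(
                roi_id=roi.roi_id,
                n_pixels=int(rows.size),
                cluster_counts=counts,
                simpson=simpson,
                similarity_median=sim_median,
            )
        )
    return profiles


@dataclass
class RankCorrelation:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def roi_size_cluster_correlation(
    profiles: Sequence[HeterogeneityProfile], level: int
) -> RankCorrelation:
    """Spearman correlation between ROI pixel count and its cluster count."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 ROI profiles")
    sizes = np.array([p.n_pixels for p in profiles], dtype=float)
    ks = np.array([p.cluster_counts[level] for p in profiles], dtype=float)
    if np.all(ks == ks[0]) or np.all(sizes == sizes[0]):
        return RankCorrelation(rho=np.nan, p_value=np.nan, n=len(profiles), defined=False)
    rho, p = sps.spearmanr(sizes, ks)
    return RankCorrelation(rho=float(rho), p_value=float(p), n=len(profiles))
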