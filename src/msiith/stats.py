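"""Group-level nonparametric inference and effect-size screening.

Pixel-level contrasts use Cohen's d (pooled-SD standardized mean
difference); ROI-level group comparisons use the Wilcoxon rank-sum test
(exact for small tie-free samples, otherwise tie- and continuity-corrected
normal approximation) with Pallant's r = |z|/sqrt(N), and the
Kruskal-Wallis test with eta-squared plus the Conover-Iman posthoc for
four-group contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .components import FeatureMatrix
from .datatypes import ClinicalRecord
from .divik import LevelLabels
from .metrics import HeterogeneityProfile

logger = logging.getLogger("msiith")

__all__ = [
    "TestResult",
    "EffectSizeRecord",
    "ScreeningResult",
    "cohens_d",
    "classify_effect_size",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "conover_posthoc",
    "screen_components",
    "cluster_contribution",
    "correlate_tils",
    "contingency_2x2",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size: float
    effect_kind: str  # {"eta_squared", "pallant_r", "cohens_d", ...}
    group_sizes: Tuple[int, ...]
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EffectSizeRecord:
    component_id: int
    contrast: str
    d: float
    size_class: str


@dataclass
class ScreeningResult:
    selected: List[int]
    d_cluster: np.ndarray  # per-component d for target-cluster-vs-rest
    d_outcome: np.ndarray  # per-component d for ND-vs-PD
    d_cluster_min: float
    d_outcome_min: float
    target_cluster: str


# --------------------------------------------------------------------------
# Effect sizes


def classify_effect_size(d: float) -> str:
    """Conventional |d| classes: 0.2 small, 0.5 medium, 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Mean difference over the pooled standard deviation.

    ``d = (mean_a - mean_b) / s_pooled`` with
    ``s_pooled^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2)``.
    Degenerate case (both variances zero): 0 for equal means, signed
    infinity otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled == 0:
        if diff == 0:
            return 0.0
        logger.warning("degenerate Cohen's d: zero pooled variance, unequal means")
        return float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled))


def _cohens_d_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Cohen's d between two row-blocks (vectorized)."""
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    diff = A.mean(axis=0) - B.mean(axis=0)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / np.sqrt(pooled)
    d = np.where(pooled == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), d)
    return d


# --------------------------------------------------------------------------
# Rank tests


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Tie-corrected, continuity-corrected z for the Mann-Whitney U of a."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return u1, 0.0
    cc = 0.5 * np.sign(u1 - mu)
    z = (u1 - mu - cc) / np.sqrt(var)
    return u1, float(z)


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``exact`` enumerates the permutation distribution (only valid for
    tie-free data; used automatically when N <= 12 without ties), otherwise
    the normal approximation with tie and continuity corrections applies.
    Pallant's r = |z|/sqrt(N) is attached in both modes.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n = pooled.size
    if mode == "auto":
        mode = "exact" if (n <= 12 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        logger.warning("ties present; falling back to normal approximation")
        mode = "normal"

    u1, z = _rank_sum_z(a, b)
    if mode == "exact":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        stat = float(res.statistic)
    elif mode == "normal":
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(p, 1.0)
        stat = u1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r = abs(z) / np.sqrt(n)
    return TestResult(
        test_name=f"wilcoxon_rank_sum[{mode}]",
        statistic=stat,
        p_value=p,
        effect_size=float(r),
        effect_kind="pallant_r",
        group_sizes=(int(a.size), int(b.size)),
        extra={"z": z},
    )


def pallant_r(z: float, n_total: int) -> float:
    return abs(z) / np.sqrt(n_total)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df and
    eta-squared ``(H - k + 1) / (N - k)`` attached."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    k = len(arrays)
    N = pooled.size
    if np.all(pooled == pooled[0]):
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, float((0.0 - k + 1) / (N - k)),
            "eta_squared", tuple(g.size for g in arrays),
        )
    H, p = sps.kruskal(*arrays)
    eta2 = (H - k + 1) / (N - k)
    return TestResult(
        test_name="kruskal_wallis",
        statistic=float(H),
        p_value=float(p),
        effect_size=float(eta2),
        effect_kind="eta_squared",
        group_sizes=tuple(int(g.size) for g in arrays),
    )


def conover_posthoc(
    groups: Sequence[Sequence[float]],
    holm_adjust: bool = False,
) -> List[TestResult]:
    """Conover-Iman pairwise comparisons on pooled ranks after
    Kruskal-Wallis.

    ``t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 ((N-1-H)/(N-k)) (1/n_i + 1/n_j))``
    with the tie-aware rank variance ``S^2``; two-sided p from Student's t
    with N-k df.  Pallant's r per pair derives from the p-value's
    z-equivalent and the pair's joint size.  No multiplicity adjustment by
    default; Holm available by flag.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 3:
        raise ValueError("posthoc needs at least 3 groups")
    pooled = np.concatenate(arrays)
    N = pooled.size
    k = len(arrays)
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in arrays]
    for i, sz in enumerate(sizes):
        if sz == 1:
            logger.warning("group %d has a single observation; comparisons are low-power", i)
    bounds = np.cumsum([0] + sizes)
    rbar = np.array([ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)])
    if np.all(pooled == pooled[0]):
        H = 0.0
    else:
        H, _ = sps.kruskal(*arrays)
    S2 = (np.sum(ranks**2) - N * (N + 1.0) ** 2 / 4.0) / (N - 1.0)
    factor = max((N - 1.0 - H) / (N - k), np.finfo(float).tiny)
    df = N - k
    out: List[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(S2 * factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = (rbar[i] - rbar[j]) / se if se > 0 else 0.0
            p = float(2.0 * sps.t.sf(abs(t), df))
            p = min(p, 1.0)
            pair_n = sizes[i] + sizes[j]
            z_eq = sps.norm.isf(max(p / 2.0, 1e-300))
            r = min(abs(z_eq) / np.sqrt(pair_n), 1.0)
            out.append(
                TestResult(
                    test_name="conover",
                    statistic=float(t),
                    p_value=p,
                    effect_size=float(max(r, 0.0)),
                    effect_kind="pallant_r",
                    group_sizes=(sizes[i], sizes[j]),
                    extra={"pair": (i, j), "df": df},
                )
            )
    if holm_adjust:
        order = np.argsort([t.p_value for t in out])
        m = len(out)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min((m - rank) * out[idx].p_value, 1.0)
            running = max(running, adj)
            out[idx].extra["p_holm"] = running
    return out


# --------------------------------------------------------------------------
# Screening and cohort-level contrasts


def screen_components(
    features: FeatureMatrix,
    level1_labels: LevelLabels,
    target_cluster: str,
    outcome_per_pixel: np.ndarray,
    d_cluster_min: float = 0.5,
    d_outcome_min: float = 0.2,
) -> ScreeningResult:
    """Select components that separate the target cluster from the rest
    (|d| >= d_cluster_min) AND the ND from the PD pixels
    (|d| >= d_outcome_min)."""
    labels = np.asarray(level1_labels.labels)
    in_cluster = labels == target_cluster
    if in_cluster.sum() < 2:
        raise ValueError(f"target cluster {target_cluster!r} has < 2 pixels")
    out_cluster = ~in_cluster
    nd = outcome_per_pixel == "ND"
    pd_ = outcome_per_pixel == "PD"
    X = features.values
    d_cluster = _cohens_d_matrix(X[in_cluster], X[out_cluster])
    d_outcome = _cohens_d_matrix(X[nd], X[pd_])
    selected = [
        int(c.component_id)
        for c, dc, do in zip(features.components, d_cluster, d_outcome)
        if abs(dc) >= d_cluster_min and abs(do) >= d_outcome_min
    ]
    return ScreeningResult(
        selected=selected,
        d_cluster=d_cluster,
        d_outcome=d_outcome,
        d_cluster_min=d_cluster_min,
        d_outcome_min=d_outcome_min,
        target_cluster=target_cluster,
    )


def cluster_contribution(
    roi_labels: Dict[str, np.ndarray],
    cluster: str,
    roi_outcome: Dict[str, str],
) -> Tuple[Dict[str, float], TestResult]:
    """Per-ROI fraction of pixels in a cluster, plus the ND-vs-PD Wilcoxon
    comparison of those fractions."""
    fractions = {}
    for roi_id, labels in roi_labels.items():
        labels = np.asarray(labels)
        fractions[roi_id] = float((labels == cluster).sum() / labels.size)
    nd = [fractions[r] for r in fractions if roi_outcome[r] == "ND"]
    pd_ = [fractions[r] for r in fractions if roi_outcome[r] == "PD"]
    test = wilcoxon_rank_sum(nd, pd_) if nd and pd_ else None
    return fractions, test


@dataclass
class TilsResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    slope_stderr: float
    slope_ci95: Tuple[float, float]
    n: int
    group_test: Optional[TestResult]
    group_d: Optional[float]
    defined: bool = True


def correlate_tils(
    profiles: Sequence[HeterogeneityProfile],
    metadata: Sequence[ClinicalRecord],
    level: int = 1,
    roi_patient: Optional[Dict[str, str]] = None,
) -> TilsResult:
    """Pearson correlation between TILs percentage and the Simpson diversity
    at a level, with the least-squares line and its 95% CI band parameters,
    plus the ND-vs-PD comparison of TILs."""
    by_patient = {m.patient_id: m for m in metadata}
    xs, ys, outcomes = [], [], []
    for prof in profiles:
        pid = roi_patient.get(prof.roi_id, prof.roi_id) if roi_patient else prof.roi_id
        rec = by_patient.get(pid)
        if rec is None or rec.tils_percent is None:
            continue
        xs.append(prof.simpson[level])
        ys.append(rec.tils_percent)
        outcomes.append(rec.outcome)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 patients with TILs scores, got {len(xs)}")
    x = np.array(xs)
    y = np.array(ys)
    if np.all(y == y[0]) or np.all(x == x[0]):
        return TilsResult(np.nan, np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                          len(xs), None, None, defined=False)
    lr = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, len(xs) - 2)
    ci = (lr.slope - tcrit * lr.stderr, lr.slope + tcrit * lr.stderr)
    nd = y[np.array(outcomes) == "ND"]
    pd_ = y[np.array(outcomes) == "PD"]
    gt = wilcoxon_rank_sum(nd, pd_) if nd.size and pd_.size else None
    gd = cohens_d(nd, pd_) if nd.size >= 2 and pd_.size >= 2 else None
    return TilsResult(
        r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        slope_stderr=float(lr.stderr),
        slope_ci95=ci,
        n=len(xs),
        group_test=gt,
        group_d=gd,
    )


def contingency_2x2(table: np.ndarray) -> Dict[str, float]:
    """Chi-square (with continuity correction) and Fisher exact p for a
    2x2 contingency table — utility for categorical group composition."""
    table = np.asarray(table)
    chi2, p_chi, _, _ = sps.chi2_contingency(table, correction=True)
    _, p_fisher = sps.fisher_exact(table)
    return {"chi2": float(chi2), "p_chi2": float(p_chi), "p_fisher": float(p_fisher)}
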