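"""Gaussian-mixture decomposition of the cohort mean spectrum into spectral
components, and projection of pixel spectra onto those components.

The mean spectrum is treated as an unnormalized 1-D density over m/z: the
axis is first cut into independent fragments at low-signal valleys, then a
weighted EM fits a small Gaussian mixture per fragment with BIC model
selection.  Each resulting Gaussian (center, sigma, area) is one spectral
component / feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .datatypes import CohortDataset, ComponentsConfig, MassAxis

logger = logging.getLogger("msiith")

__all__ = [
    "SpectralComponent",
    "FeatureMatrix",
    "segment_spectrum",
    "fit_gmm_components",
    "compute_feature_matrix",
    "write_components_csv",
    "read_components_csv",
    "write_feature_matrix",
    "read_feature_matrix",
]


@dataclass(frozen=True)
class SpectralComponent:
    component_id: int
    center: float  # m/z, Da
    sigma: float  # m/z width, Da
    amplitude: float  # integrated area in the mean spectrum (intensity x Da)
    channel_range: Tuple[int, int]  # [lo, hi) covering center +/- 3 sigma

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.channel_range[1] <= self.channel_range[0]:
            raise ValueError("channel_range must be nonempty")


@dataclass
class FeatureMatrix:
    """Per-pixel component abundances with row provenance."""

    values: np.ndarray  # N x K, nonnegative
    components: List[SpectralComponent]
    roi_ids: np.ndarray  # N, str
    coordinates: np.ndarray  # N x 2

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(self.components):
            raise ValueError("feature matrix shape does not match component list")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_pixels(self) -> int:
        return int(self.values.shape[0])

    def rows_of(self, roi_id: str) -> np.ndarray:
        return np.flatnonzero(self.roi_ids == roi_id)


# --------------------------------------------------------------------------


def segment_spectrum(
    mean: np.ndarray, axis: MassAxis, min_valley_rel: float = 0.01
) -> List[Tuple[int, int]]:
    """Split the axis at valleys below ``min_valley_rel * max(mean)``.

    Returns disjoint ``[lo, hi)`` channel intervals covering all channels
    with signal; a flat zero spectrum yields no fragments.
    """
    mean = np.asarray(mean, dtype=np.float64)
    mx = mean.max(initial=0.0)
    if mx <= 0:
        return []
    mask = mean > min_valley_rel * mx
    fragments = []
    lo = None
    for i, on in enumerate(mask):
        if on and lo is None:
            lo = i
        elif not on and lo is not None:
            fragments.append((lo, i))
            lo = None
    if lo is not None:
        fragments.append((lo, mask.size))
    return fragments


def _weighted_em(
    x: np.ndarray,
    w: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    sigma_floor: float,
    init_mu: Optional[np.ndarray] = None,
) -> Optional[Tuple[np.ndarray, np.ndarray, np.ndarray, float]]:
    """EM for a k-component 1-D Gaussian mixture under channel weights.

    Returns (weights, means, sigmas, weighted log-likelihood) or None on
    numerical failure.
    """
    W = w.sum()
    if init_mu is not None and init_mu.size == k:
        mu = np.sort(init_mu.astype(np.float64))
    else:
        # quantile initialization of the weighted distribution, with jitter
        cdf = np.cumsum(w) / W
        qs = (np.arange(k) + 0.5) / k + rng.uniform(-0.2, 0.2, size=k) / k
        mu = np.interp(np.clip(qs, 0.0, 1.0), cdf, x)
    span = x[-1] - x[0] if x.size > 1 else 1.0
    sig = np.full(k, max(min(span / (2.0 * k), 3.0 * sigma_floor), sigma_floor))
    pi = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        z = (x[:, None] - mu[None, :]) / sig[None, :]
        log_pdf = -0.5 * z**2 - np.log(sig[None, :] * np.sqrt(2 * np.pi))
        log_w = np.log(np.maximum(pi, 1e-300))[None, :] + log_pdf
        m = log_w.max(axis=1, keepdims=True)
        p = np.exp(log_w - m)
        denom = p.sum(axis=1, keepdims=True)
        resp = p / denom
        ll = float((w * (m.ravel() + np.log(denom.ravel()))).sum())
        if not np.isfinite(ll):
            return None
        # M step
        nk = (w[:, None] * resp).sum(axis=0)
        if (nk <= 0).any():
            return None
        pi = nk / W
        mu = (w[:, None] * resp * x[:, None]).sum(axis=0) / nk
        var = (w[:, None] * resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sig = np.sqrt(np.maximum(var, sigma_floor**2))
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return pi, mu, sig, prev_ll


def _moment_fit(x: np.ndarray, w: np.ndarray, sigma_floor: float):
    W = w.sum()
    mu = float((w * x).sum() / W)
    var = float((w * (x - mu) ** 2).sum() / W)
    return np.array([1.0]), np.array([mu]), np.array([max(np.sqrt(var), sigma_floor)])


def _local_maxima(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fragment apex locations ordered by height (EM initialization)."""
    from scipy.signal import find_peaks

    idx, props = find_peaks(w, prominence=0.01 * w.max())
    if idx.size == 0:
        idx = np.array([int(np.argmax(w))])
        return x[idx]
    order = np.argsort(w[idx])[::-1]
    return x[idx[order]]


def _fit_fragment(
    x: np.ndarray,
    w: np.ndarray,
    cfg: ComponentsConfig,
    rng: np.random.Generator,
    sigma_floor: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BIC scan over mixture sizes for one fragment; returns (pi, mu, sigma).

    Intensities act as pseudo-counts (ToF spectra are ion counts), so the
    BIC sample size is the fragment's total intensity; the first EM start
    seeds means at the fragment's apex positions.
    """
    n = x.size
    log_n = np.log(max(w.sum(), 2.0))
    apexes = _local_maxima(x, w)
    k_cap = int(min(cfg.max_components_per_fragment, max(1, n // 3), apexes.size + 2))
    best = None
    best_bic = np.inf
    rises = 0
    for k in range(1, k_cap + 1):
        fit = None
        for r in range(cfg.n_restarts + 1):
            init = apexes[:k] if (r == 0 and apexes.size >= k) else None
            cand = _weighted_em(
                x, w, k, rng, cfg.em_max_iter, cfg.em_tol, sigma_floor, init_mu=init
            )
            if cand is not None and (fit is None or cand[3] > fit[3]):
                fit = cand
        if fit is None:
            continue
        pi, mu, sig, ll = fit
        bic = -2.0 * ll + (3 * k - 1) * log_n
        if bic < best_bic:
            best_bic = bic
            best = (pi, mu, sig)
            rises = 0
        else:
            rises += 1
            if rises >= 3:  # BIC clearly past its minimum: stop scanning
                break
    if best is None:
        logger.warning("EM failed to converge in fragment; using moment fit")
        best = _moment_fit(x, w, sigma_floor)
    return best


def _merge_close(
    areas: np.ndarray, mus: np.ndarray, sigs: np.ndarray, merge_sigma: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moment-matching merge of neighbors closer than merge_sigma*min(sigma)."""
    order = np.argsort(mus)
    a, m, s = list(areas[order]), list(mus[order]), list(sigs[order])
    i = 0
    while i < len(m) - 1:
        if abs(m[i + 1] - m[i]) < merge_sigma * min(s[i], s[i + 1]):
            A = a[i] + a[i + 1]
            mu = (a[i] * m[i] + a[i + 1] * m[i + 1]) / A
            second = (
                a[i] * (s[i] ** 2 + m[i] ** 2) + a[i + 1] * (s[i + 1] ** 2 + m[i + 1] ** 2)
            ) / A
            a[i], m[i], s[i] = A, mu, np.sqrt(max(second - mu**2, 1e-12))
            del a[i + 1], m[i + 1], s[i + 1]
        else:
            i += 1
    return np.array(a), np.array(m), np.array(s)


def fit_gmm_components(
    mean: np.ndarray,
    axis: MassAxis,
    config: Optional[ComponentsConfig] = None,
    seed: int = 0,
) -> List[SpectralComponent]:
    """Decompose a preprocessed mean spectrum into Gaussian components.

    Per valley-delimited fragment, a weighted EM with BIC model choice fits
    the intensity profile; low-amplitude components are discarded and
    near-coincident ones merged by moment matching.  Deterministic for a
    given seed.
    """
    cfg = config or ComponentsConfig()
    mean = np.asarray(mean, dtype=np.float64)
    fragments = segment_spectrum(mean, axis, cfg.min_valley_rel)
    spacing = axis.spacing
    sigma_floor = spacing / 2.0
    rng = np.random.default_rng(seed)

    areas: List[float] = []
    mus: List[float] = []
    sigs: List[float] = []
    for lo, hi in fragments:
        x = axis.values[lo:hi]
        w = mean[lo:hi]
        W = w.sum()
        if W <= 0 or x.size < 2:
            continue
        frag_area = W * spacing
        pi, mu, sig = _fit_fragment(x, w, cfg, rng, sigma_floor)
        comp_areas = pi * frag_area
        keep = comp_areas >= cfg.amplitude_floor_rel * comp_areas.max()
        comp_areas, mu, sig = comp_areas[keep], mu[keep], sig[keep]
        comp_areas, mu, sig = _merge_close(comp_areas, mu, sig, cfg.merge_sigma)
        areas.extend(comp_areas)
        mus.extend(mu)
        sigs.extend(sig)

    order = np.argsort(mus)
    components = []
    for cid, j in enumerate(order):
        c, s, a = float(mus[j]), float(sigs[j]), float(areas[j])
        lo = int(np.searchsorted(axis.values, c - 3 * s))
        hi = int(np.searchsorted(axis.values, c + 3 * s))
        lo = min(lo, len(axis) - 1)
        hi = max(hi, lo + 1)
        components.append(SpectralComponent(cid, c, s, a, (lo, hi)))
    return components


# --------------------------------------------------------------------------


def _component_weights(
    components: Sequence[SpectralComponent], axis: MassAxis
) -> List[Tuple[slice, np.ndarray]]:
    """Peak-normalized Gaussian channel weights, renormalized channel-wise so
    overlapping components never claim more than the full channel signal."""
    C = len(axis)
    raw = []
    total = np.zeros(C)
    for comp in components:
        lo, hi = comp.channel_range
        if lo < 0 or hi > C:
            raise ValueError(
                f"component {comp.component_id} channel range {comp.channel_range} "
                f"outside axis of length {C}"
            )
        x = axis.values[lo:hi]
        w = np.exp(-0.5 * ((x - comp.center) / comp.sigma) ** 2)
        raw.append((slice(lo, hi), w))
        total[lo:hi] += w
    scale = np.maximum(total, 1.0)  # only shrink where components overlap
    return [(sl, w / scale[sl]) for sl, w in raw]


def compute_feature_matrix(
    cohort: CohortDataset,
    components: Sequence[SpectralComponent],
) -> FeatureMatrix:
    """Project every pixel spectrum onto the component weight profiles.

    abundance(pixel, component) = sum over the component's channel range of
    intensity x its (sub-unity, overlap-renormalized) Gaussian weight; hence
    the abundances of one pixel never sum above its TIC.
    """
    if not components:
        raise ValueError("component list is empty")
    weights = _component_weights(components, cohort.axis)
    blocks = []
    roi_ids = []
    coords = []
    for roi in cohort.rois:
        I = roi.intensities
        F = np.empty((I.shape[0], len(components)))
        for k, (sl, w) in enumerate(weights):
            F[:, k] = I[:, sl] @ w
        blocks.append(F)
        roi_ids.extend([roi.roi_id] * roi.n_pixels)
        coords.append(roi.coordinates)
    return FeatureMatrix(
        values=np.vstack(blocks),
        components=list(components),
        roi_ids=np.array(roi_ids, dtype=object),
        coordinates=np.vstack(coords),
    )


# --------------------------------------------------------------------------
# Persistence


def write_components_csv(components: Sequence[SpectralComponent], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["component_id", "center", "sigma", "amplitude", "channel_lo", "channel_hi"])
        for c in components:
            w.writerow([c.component_id, repr(c.center), repr(c.sigma), repr(c.amplitude), *c.channel_range])


def read_components_csv(path) -> List[SpectralComponent]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SpectralComponent(
                    int(row["component_id"]),
                    float(row["center"]),
                    float(row["sigma"]),
                    float(row["amplitude"]),
                    (int(row["channel_lo"]), int(row["channel_hi"])),
                )
            )
    return out


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "msiith-features"
        f.create_dataset("values", data=fm.values)
        f.create_dataset("roi_ids", data=np.array([str(r) for r in fm.roi_ids], dtype=h5py.string_dtype("utf-8")))
        f.create_dataset("coordinates", data=fm.coordinates)
        comp = np.array(
            [
                (c.component_id, c.center, c.sigma, c.amplitude, c.channel_range[0], c.channel_range[1])
                for c in fm.components
            ]
        )
        f.create_dataset("components", data=comp)


def read_feature_matrix(path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][:]
        roi_ids = np.array([r.decode() for r in f["roi_ids"][:]], dtype=object)
        coords = f["coordinates"][:]
        comps = [
            SpectralComponent(int(r[0]), r[1], r[2], r[3], (int(r[4]), int(r[5])))
            for r in f["components"][:]
        ]
    return FeatureMatrix(values, comps, roi_ids, coords)
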