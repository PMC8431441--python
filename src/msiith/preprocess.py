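"""Spectra processing chain: mass-channel unification, baseline subtraction,
outlier-spectrum identification, peak alignment, TIC normalization, and the
cohort mean spectrum.

The fixed stage order is unify -> baseline -> outliers -> align -> normalize.
Outlier flagging precedes alignment so outlying spectra cannot distort the
alignment reference; flagged pixels are dropped from the processed cohort but
fully accounted for in the QC report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.mixture import GaussianMixture

from .datatypes import CohortDataset, MassAxis, PreprocessingConfig, ROIDataset

logger = logging.getLogger("msiith")

__all__ = [
    "QCReport",
    "unify_mass_axis",
    "subtract_baseline",
    "detect_outlier_spectra",
    "align_peaks",
    "normalize_tic",
    "mean_spectrum",
    "preprocess_cohort",
]

MAD_SCALE = 1.4826  # consistency constant for a normal distribution


@dataclass
class ROIAccounting:
    n_input: int
    n_flagged: int
    n_retained: int
    shifts: np.ndarray  # per retained pixel, applied channel shift
    tic_pre: Tuple[float, float, float]  # (min, median, max) before normalization
    tic_post: Tuple[float, float, float]

    def __post_init__(self):
        assert self.n_retained == self.n_input - self.n_flagged


@dataclass
class QCReport:
    per_roi: Dict[str, ROIAccounting] = field(default_factory=dict)
    max_shift: int = 0

    def validate(self) -> None:
        for roi_id, acc in self.per_roi.items():
            if acc.n_retained != acc.n_input - acc.n_flagged:
                raise AssertionError(f"QC accounting broken for {roi_id}")
            if acc.shifts.size and np.abs(acc.shifts).max() > self.max_shift:
                raise AssertionError(f"shift beyond limit for {roi_id}")

    def to_rows(self) -> List[dict]:
        rows = []
        for roi_id in sorted(self.per_roi):
            acc = self.per_roi[roi_id]
            rows.append(
                {
                    "roi_id": roi_id,
                    "n_input": acc.n_input,
                    "n_flagged": acc.n_flagged,
                    "n_retained": acc.n_retained,
                    "tic_pre_median": acc.tic_pre[1],
                    "tic_post_median": acc.tic_post[1],
                }
            )
        return rows


# --------------------------------------------------------------------------


def unify_mass_axis(roi: ROIDataset, target: MassAxis) -> ROIDataset:
    """Linearly interpolate the ROI's spectra onto a target axis.

    The target must lie within the span of the source axis — unification
    never extrapolates.
    """
    src = roi.axis
    if target == src:
        return roi
    if target.values[0] < src.values[0] or target.values[-1] > src.values[-1]:
        raise ValueError(
            f"target axis [{target.values[0]}, {target.values[-1]}] extends "
            f"beyond source [{src.values[0]}, {src.values[-1]}]"
        )
    # one interpolation stencil shared by all pixels
    idx = np.searchsorted(src.values, target.values, side="right") - 1
    idx = np.clip(idx, 0, len(src) - 2)
    x0 = src.values[idx]
    x1 = src.values[idx + 1]
    w = (target.values - x0) / (x1 - x0)
    out = roi.intensities[:, idx] * (1 - w) + roi.intensities[:, idx + 1] * w
    np.clip(out, 0.0, None, out=out)
    return ROIDataset(roi.roi_id, roi.patient_id, roi.coordinates, out, target)


def estimate_baseline(spectra: np.ndarray, window: int) -> np.ndarray:
    """SNIP-style smooth floor: iterative clipping with growing half-window.

    The estimate starts at the signal itself and can only decrease, so it is
    pointwise <= the input everywhere and equals it at peak-free channels.
    Accepts a single spectrum or a P x C matrix.
    """
    single = spectra.ndim == 1
    b = np.atleast_2d(spectra).astype(np.float64, copy=True)
    C = b.shape[1]
    for m in range(1, min(window, C - 1) + 1):
        padded = np.pad(b, ((0, 0), (m, m)), mode="edge")
        avg = 0.5 * (padded[:, : -2 * m] + padded[:, 2 * m :])
        np.minimum(b, avg, out=b)
    return b[0] if single else b


def subtract_baseline(spectrum: np.ndarray, config: PreprocessingConfig) -> np.ndarray:
    """``max(0, spectrum - smooth floor)``; all-zero input is returned as-is."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if not spectrum.any():
        return spectrum.copy()
    base = estimate_baseline(spectrum, config.baseline_window)
    return np.clip(spectrum - base, 0.0, None)


def _log_tic(intensities: np.ndarray) -> np.ndarray:
    tic = intensities.sum(axis=1)
    return np.log(np.maximum(tic, np.finfo(float).tiny))


def detect_outlier_spectra(
    roi: ROIDataset, config: PreprocessingConfig
) -> np.ndarray:
    """Boolean per-pixel outlier flags from the log-TIC distribution.

    ``mad`` rule: flag ``|x - median| > mad_k * 1.4826 * MAD``.  ``gmm``
    rule: fit a 1-3 component univariate mixture (BIC-selected, seeded EM)
    and flag pixels assigned to any component whose mean lies more than one
    dominant-component standard deviation below the dominant mean.
    """
    if roi.n_pixels < 10:
        raise ValueError(
            f"ROI {roi.roi_id!r} has {roi.n_pixels} pixels (< 10); too few for "
            "distribution fitting — apply the mad rule on the pooled cohort"
        )
    x = _log_tic(roi.intensities)
    if config.outlier_rule == "mad":
        return _mad_flags(x, config.mad_k)
    if config.outlier_rule == "gmm":
        return _gmm_flags(x)
    raise ValueError(f"unknown outlier rule {config.outlier_rule!r}")


def _mad_flags(x: np.ndarray, k: float) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return np.abs(x - med) > k * MAD_SCALE * mad


def _gmm_flags(x: np.ndarray) -> np.ndarray:
    if np.allclose(x, x[0]):
        return np.zeros(x.size, dtype=bool)
    X = x[:, None]
    best = None
    best_bic = np.inf
    for k in (1, 2, 3):
        if k >= x.size:
            break
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=0, n_init=2,
            reg_covar=1e-9,
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best_bic = bic
            best = gm
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.reshape(-1))
    dominant = int(np.argmax(best.weights_))
    bad = means < means[dominant] - sds[dominant]
    if not bad.any():
        return np.zeros(x.size, dtype=bool)
    assign = best.predict(X)
    return bad[assign]


def align_peaks(
    roi: ROIDataset,
    config: PreprocessingConfig,
    flags: Optional[np.ndarray] = None,
    reference: Optional[np.ndarray] = None,
) -> Tuple[ROIDataset, np.ndarray]:
    """Rigid integer-channel alignment against the unflagged mean spectrum.

    Each spectrum is shifted by the offset (|offset| <= alignment_max_shift)
    maximizing its cross-correlation with the reference; ties prefer the
    smaller |offset| so degenerate flat spectra keep shift 0.  Vacated edge
    channels are zero-filled.
    """
    L = int(config.alignment_max_shift)
    I = roi.intensities
    P, C = I.shape
    if flags is None:
        flags = np.zeros(P, dtype=bool)
    if reference is None:
        keep = ~flags
        reference = I[keep].mean(axis=0) if keep.any() else I.mean(axis=0)
    if L == 0:
        return roi, np.zeros(P, dtype=np.int64)

    offsets = sorted(range(-L, L + 1), key=abs)  # 0 first -> wins ties
    scores = np.empty((len(offsets), P))
    for oi, s in enumerate(offsets):
        if s == 0:
            scores[oi] = I @ reference
        elif s > 0:  # spectrum moved right by s: spec[i] vs ref[i + s]... no:
            # shifted(spec, s)[i] = spec[i - s]; dot with ref over valid region
            scores[oi] = I[:, : C - s] @ reference[s:]
        else:
            scores[oi] = I[:, -s:] @ reference[: C + s]
    best = np.argmax(scores, axis=0)  # first max wins -> smallest |offset|
    shifts = np.array([offsets[b] for b in best], dtype=np.int64)

    out = np.zeros_like(I)
    for s in np.unique(shifts):
        rows = shifts == s
        if s == 0:
            out[rows] = I[rows]
        elif s > 0:
            out[rows, s:] = I[rows][:, : C - s]
        else:
            out[rows, :s] = I[rows][:, -s:]
    aligned = ROIDataset(roi.roi_id, roi.patient_id, roi.coordinates, out, roi.axis)
    return aligned, shifts


def normalize_tic(
    roi: ROIDataset,
    config: PreprocessingConfig,
    target: Optional[float] = None,
    flags: Optional[np.ndarray] = None,
) -> ROIDataset:
    """Scale each unflagged spectrum so its TIC equals the target.

    ``target=None`` resolves the configured policy on this ROI alone
    (median TIC of its unflagged pixels, or 1.0 for ``unity``); the cohort
    pipeline passes the dataset-wide median explicitly.
    """
    tic = roi.intensities.sum(axis=1)
    if flags is None:
        flags = np.zeros(roi.n_pixels, dtype=bool)
    unflagged = ~flags
    zero = unflagged & (tic <= 0)
    if zero.any():
        px = int(np.argmax(zero))
        raise ValueError(
            f"zero-TIC unflagged spectrum at pixel index {px} "
            f"(coordinates {tuple(roi.coordinates[px])}) in ROI {roi.roi_id!r}"
        )
    if target is None:
        target = 1.0 if config.tic_target == "unity" else float(np.median(tic[unflagged]))
    scale = np.ones_like(tic)
    scale[unflagged] = target / tic[unflagged]
    out = roi.intensities * scale[:, None]
    return ROIDataset(roi.roi_id, roi.patient_id, roi.coordinates, out, roi.axis)


def mean_spectrum(
    cohort: CohortDataset, flags: Optional[Dict[str, np.ndarray]] = None
) -> np.ndarray:
    """Channel-wise arithmetic mean over all unflagged pixels of all ROIs."""
    total = np.zeros(len(cohort.axis))
    count = 0
    for roi in cohort.rois:
        f = None if flags is None else flags.get(roi.roi_id)
        if f is None:
            total += roi.intensities.sum(axis=0)
            count += roi.n_pixels
        else:
            keep = ~f
            total += roi.intensities[keep].sum(axis=0)
            count += int(keep.sum())
    if count == 0:
        raise ValueError("no unflagged pixels in cohort")
    return total / count


# --------------------------------------------------------------------------


def preprocess_cohort(
    cohort: CohortDataset,
    config: Optional[PreprocessingConfig] = None,
    target_axis: Optional[MassAxis] = None,
) -> Tuple[CohortDataset, QCReport]:
    """Run the full chain on a cohort; flagged pixels are removed from the
    returned cohort and accounted for in the QC report."""
    config = config or PreprocessingConfig()
    report = QCReport(max_shift=config.alignment_max_shift)

    staged: List[ROIDataset] = []
    flags_all: Dict[str, np.ndarray] = {}
    for roi in cohort.rois:
        if target_axis is not None:
            roi = unify_mass_axis(roi, target_axis)
        floor = estimate_baseline(roi.intensities, config.baseline_window)
        debased = np.clip(roi.intensities - floor, 0.0, None)
        roi = ROIDataset(roi.roi_id, roi.patient_id, roi.coordinates, debased, roi.axis)
        try:
            flags = detect_outlier_spectra(roi, config)
        except ValueError:
            logger.warning(
                "ROI %s too small for per-ROI outlier fitting; using mad rule",
                roi.roi_id,
            )
            flags = _mad_flags(_log_tic(roi.intensities), config.mad_k)
        flags_all[roi.roi_id] = flags
        staged.append(roi)

    aligned: List[ROIDataset] = []
    shifts_all: Dict[str, np.ndarray] = {}
    for roi in staged:
        roi2, shifts = align_peaks(roi, config, flags=flags_all[roi.roi_id])
        aligned.append(roi2)
        shifts_all[roi.roi_id] = shifts

    # dataset-wide target TIC over unflagged pixels
    tics = []
    for roi in aligned:
        keep = ~flags_all[roi.roi_id]
        tics.append(roi.intensities[keep].sum(axis=1))
    pooled = np.concatenate(tics)
    target = 1.0 if config.tic_target == "unity" else float(np.median(pooled))

    out_rois: List[ROIDataset] = []
    for roi in aligned:
        flags = flags_all[roi.roi_id]
        tic_pre = roi.intensities[~flags].sum(axis=1)
        roi2 = normalize_tic(roi, config, target=target, flags=flags)
        keep = ~flags
        kept = ROIDataset(
            roi.roi_id,
            roi.patient_id,
            roi2.coordinates[keep],
            roi2.intensities[keep],
            roi2.axis,
        )
        out_rois.append(kept)
        tic_post = kept.intensities.sum(axis=1)
        report.per_roi[roi.roi_id] = ROIAccounting(
            n_input=roi.n_pixels,
            n_flagged=int(flags.sum()),
            n_retained=kept.n_pixels,
            shifts=shifts_all[roi.roi_id][keep],
            tic_pre=(float(tic_pre.min()), float(np.median(tic_pre)), float(tic_pre.max())),
            tic_post=(float(tic_post.min()), float(np.median(tic_post)), float(tic_post.max())),
        )

    report.validate()
    return CohortDataset(out_rois, cohort.metadata), report
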