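"""Synthetic MSI cohort generation with planted ground truth.

Spectra are sums of Gaussian peptide peaks whose amplitudes depend on a
planted spatial sub-region map.  Region expression profiles are drawn from a
small shared pool of archetypes so that pooled clustering across ROIs can
recover them; the number of regions per ROI is group-dependent, which plants
a group-level heterogeneity difference.  A shared "core" profile dominates
and only a configurable fraction of peaks is region-modulated, so pixel
spectra stay highly similar overall.

All randomness flows from one seed through ``numpy.random.SeedSequence``
substreams (cohort-level stream + one stream per ROI), so regeneration is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .annotate import PROTON_MASS, PeptideEntry
from .datatypes import ClinicalRecord, CohortDataset, MassAxis, ROIDataset

__all__ = ["CohortConfig", "SyntheticTruth", "generate_cohort", "generate_peptide_library"]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; all counts are desk-scale defaults."""

    n_patients_nd: int = 6
    n_patients_pd: int = 6
    roi_pixels: Tuple[int, int] = (900, 2500)  # inclusive range for P
    mz_start: float = 600.0
    mz_end: float = 3500.0
    n_channels: int = 6000
    n_peptide_peaks: int = 300
    min_peak_separation: float = 3.0  # Da between neighboring true centers
    sigma_range: Tuple[float, float] = (1.0, 2.5)  # Da
    regions_nd: Tuple[int, int] = (4, 7)  # inclusive uniform range per ROI
    regions_pd: Tuple[int, int] = (2, 3)
    n_region_archetypes: int = 8
    region_geometry: str = "voronoi"  # {"voronoi", "blobs"}
    modulated_fraction: float = 0.3
    profile_effect: float = 1.5  # mean |log2| abundance shift of modulated peaks
    n_group_peaks: int = 0  # peaks additionally modulated between ND and PD
    group_effect: float = 0.0  # |log2| ND-vs-PD shift of those peaks
    tic_cv: float = 0.15  # CV of per-pixel multiplicative gain
    baseline_amp: float = 2.0
    noise_sd: float = 0.5
    outlier_fraction: float = 0.0  # pixels with gain x 0.01
    shift_channels: int = 0  # max |planted per-pixel mass shift| in channels
    tils_fraction: float = 0.6  # fraction of patients with a TILs score
    seed: int = 0

    def __post_init__(self):
        if self.n_patients_nd < 1 or self.n_patients_pd < 1:
            raise ValueError("need at least one patient per group")
        if not (0 <= self.modulated_fraction <= 1):
            raise ValueError("modulated_fraction must be in [0, 1]")
        if not (0 <= self.outlier_fraction <= 1):
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.profile_effect < 0 or self.group_effect < 0:
            raise ValueError("effects must be >= 0")
        if self.regions_nd[1] > self.n_region_archetypes or (
            self.regions_pd[1] > self.n_region_archetypes
        ):
            raise ValueError("regions_per_roi cannot exceed n_region_archetypes")


@dataclass
class SyntheticTruth:
    """Planted ground truth, aligned index-for-index with the cohort."""

    peak_centers: np.ndarray  # (n_peaks,) m/z
    peak_sigmas: np.ndarray  # (n_peaks,) Da
    base_amplitudes: np.ndarray  # (n_peaks,) core profile
    modulated_mask: np.ndarray  # (n_peaks,) bool, region-modulated
    group_mask: np.ndarray  # (n_peaks,) bool, ND-vs-PD modulated
    archetype_profiles: np.ndarray  # (n_archetypes, n_peaks)
    group_factors: Dict[str, np.ndarray]  # outcome -> (n_peaks,) multiplier
    region_labels: Dict[str, np.ndarray]  # roi_id -> per-pixel archetype id
    pixel_gain: Dict[str, np.ndarray]
    pixel_shift: Dict[str, np.ndarray]  # planted channel shifts (integer)
    outlier_flags: Dict[str, np.ndarray]
    roi_outcome: Dict[str, str]
    planted_simpson: Dict[str, float]  # distinct-pairs diversity of true labels

    @property
    def n_peaks(self) -> int:
        return int(self.peak_centers.size)


def _draw_centers(rng, cfg: CohortConfig) -> np.ndarray:
    lo = cfg.mz_start + 6 * cfg.sigma_range[1]
    hi = cfg.mz_end - 6 * cfg.sigma_range[1]
    span = hi - lo
    needed = cfg.n_peptide_peaks * cfg.min_peak_separation
    if needed > span:
        raise ValueError("axis span too small for requested peak count/separation")
    # uniform with minimum gap via the order-statistics trick
    slack = span - needed
    gaps = rng.dirichlet(np.ones(cfg.n_peptide_peaks + 1)) * slack
    centers = lo + np.cumsum(gaps[:-1]) + cfg.min_peak_separation * np.arange(
        cfg.n_peptide_peaks
    )
    return centers


def _voronoi_labels(rng, coords: np.ndarray, n_regions: int) -> np.ndarray:
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    centers = rng.uniform(lo, hi + 1, size=(n_regions, 2))
    d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d.argmin(axis=1)
    # ensure every region id occurs at least once
    for r in range(n_regions):
        if not (labels == r).any():
            labels[rng.integers(coords.shape[0])] = r
    return labels


def _blob_labels(rng, coords: np.ndarray, n_regions: int) -> np.ndarray:
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    centers = rng.uniform(lo, hi + 1, size=(n_regions, 2))
    widths = rng.uniform(0.15, 0.5, size=n_regions) * max(hi - lo + 1)
    d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    dens = np.exp(-d / (2 * widths[None, :] ** 2))
    labels = dens.argmax(axis=1)
    for r in range(n_regions):
        if not (labels == r).any():
            labels[rng.integers(coords.shape[0])] = r
    return labels


def _simpson_distinct_pairs(labels: np.ndarray) -> float:
    n = labels.size
    if n < 2:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    return float(1.0 - (counts * (counts - 1.0)).sum() / (n * (n - 1.0)))


def _grid_coords(n_pixels: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_pixels)))
    ys, xs = np.divmod(np.arange(n_pixels), side)
    return np.column_stack([xs, ys]).astype(np.int64)


def _peak_templates(axis_values, centers, sigmas) -> List[Tuple[slice, np.ndarray]]:
    """Per-peak (channel slice, unit-amplitude Gaussian) with +/-5 sigma support."""
    out = []
    for c, s in zip(centers, sigmas):
        lo = np.searchsorted(axis_values, c - 5 * s)
        hi = np.searchsorted(axis_values, c + 5 * s)
        x = axis_values[lo:hi]
        out.append((slice(lo, hi), np.exp(-0.5 * ((x - c) / s) ** 2)))
    return out


def generate_cohort(config: CohortConfig) -> Tuple[CohortDataset, SyntheticTruth]:
    """Build a cohort with planted heterogeneity structure.

    Pixel spectra are ``gain * shifted(region template) + baseline + noise``
    clipped at zero, where the region template is the sum of Gaussian peaks
    with amplitudes from the pixel's region profile.
    """
    cfg = config
    axis = MassAxis.linear(cfg.mz_start, cfg.mz_end, cfg.n_channels)
    spacing = axis.spacing
    if cfg.sigma_range[0] < 2 * spacing:
        raise ValueError(
            f"peak width {cfg.sigma_range[0]:.3f} Da below 2 channel spacings "
            f"({2 * spacing:.3f} Da); axis too coarse to resolve requested peaks"
        )

    root = np.random.SeedSequence(cfg.seed)
    n_rois = cfg.n_patients_nd + cfg.n_patients_pd
    cohort_ss, *roi_ss = root.spawn(n_rois + 1)
    rng = np.random.default_rng(cohort_ss)

    centers = _draw_centers(rng, cfg)
    sigmas = rng.uniform(*cfg.sigma_range, size=cfg.n_peptide_peaks)
    base_amp = rng.lognormal(mean=3.0, sigma=0.8, size=cfg.n_peptide_peaks)

    n_mod = int(round(cfg.modulated_fraction * cfg.n_peptide_peaks))
    modulated = np.zeros(cfg.n_peptide_peaks, dtype=bool)
    modulated[rng.choice(cfg.n_peptide_peaks, size=n_mod, replace=False)] = True

    group_mask = np.zeros(cfg.n_peptide_peaks, dtype=bool)
    if cfg.n_group_peaks > 0:
        group_mask[rng.choice(cfg.n_peptide_peaks, size=cfg.n_group_peaks, replace=False)] = True

    # archetype profiles: core profile with a log2 shift on modulated peaks
    profiles = np.tile(base_amp, (cfg.n_region_archetypes, 1))
    shifts = rng.normal(0.0, 1.0, size=(cfg.n_region_archetypes, n_mod))
    shifts = np.sign(shifts) * (np.abs(shifts) + 0.5) / 1.5 * cfg.profile_effect
    profiles[:, modulated] *= 2.0 ** shifts

    group_factors = {
        "ND": np.ones(cfg.n_peptide_peaks),
        "PD": np.where(group_mask, 2.0 ** (-cfg.group_effect), 1.0),
    }

    templates = _peak_templates(axis.values, centers, sigmas)
    baseline = cfg.baseline_amp * np.exp(-(axis.values - cfg.mz_start) / 700.0)

    outcomes = ["ND"] * cfg.n_patients_nd + ["PD"] * cfg.n_patients_pd
    rois: List[ROIDataset] = []
    records: List[ClinicalRecord] = []
    truth = SyntheticTruth(
        peak_centers=centers,
        peak_sigmas=sigmas,
        base_amplitudes=base_amp,
        modulated_mask=modulated,
        group_mask=group_mask,
        archetype_profiles=profiles,
        group_factors=group_factors,
        region_labels={},
        pixel_gain={},
        pixel_shift={},
        outlier_flags={},
        roi_outcome={},
        planted_simpson={},
    )

    geometry = {"voronoi": _voronoi_labels, "blobs": _blob_labels}[cfg.region_geometry]

    for i, (outcome, ss) in enumerate(zip(outcomes, roi_ss)):
        rroi = np.random.default_rng(ss)
        roi_id = f"roi{i:03d}"
        patient_id = f"pt{i:03d}"
        n_pix = int(rroi.integers(cfg.roi_pixels[0], cfg.roi_pixels[1] + 1))
        coords = _grid_coords(n_pix)

        lo_r, hi_r = cfg.regions_nd if outcome == "ND" else cfg.regions_pd
        n_regions = int(rroi.integers(lo_r, hi_r + 1))
        local = geometry(rroi, coords, n_regions)
        arch_ids = rroi.choice(cfg.n_region_archetypes, size=n_regions, replace=False)
        labels = arch_ids[local]

        roi_profiles = profiles[arch_ids] * group_factors[outcome][None, :]
        region_templates = np.zeros((n_regions, cfg.n_channels))
        for r in range(n_regions):
            for p, (sl, tpl) in enumerate(templates):
                region_templates[r, sl] += roi_profiles[r, p] * tpl

        if cfg.tic_cv > 0:
            sig = np.sqrt(np.log1p(cfg.tic_cv**2))
            gain = rroi.lognormal(mean=-0.5 * sig**2, sigma=sig, size=n_pix)
        else:
            gain = np.ones(n_pix)
        outliers = rroi.random(n_pix) < cfg.outlier_fraction
        gain = np.where(outliers, gain * 0.01, gain)
        if cfg.shift_channels > 0:
            shifts_px = rroi.integers(-cfg.shift_channels, cfg.shift_channels + 1, size=n_pix)
        else:
            shifts_px = np.zeros(n_pix, dtype=np.int64)

        spectra = region_templates[local] * gain[:, None]
        for j in range(n_pix):
            s = int(shifts_px[j])
            if s:
                spectra[j] = np.roll(spectra[j], s)
                if s > 0:
                    spectra[j, :s] = 0.0
                else:
                    spectra[j, s:] = 0.0
        spectra += baseline[None, :]
        if cfg.noise_sd > 0:
            spectra += rroi.normal(0.0, cfg.noise_sd, size=spectra.shape)
        np.clip(spectra, 0.0, None, out=spectra)

        rois.append(ROIDataset(roi_id, patient_id, coords, spectra, axis))
        truth.region_labels[roi_id] = labels
        truth.pixel_gain[roi_id] = gain
        truth.pixel_shift[roi_id] = shifts_px
        truth.outlier_flags[roi_id] = outliers
        truth.roi_outcome[roi_id] = outcome
        truth.planted_simpson[roi_id] = _simpson_distinct_pairs(labels)

        has_tils = rroi.random() < cfg.tils_fraction
        tils = None
        if has_tils:
            tils = float(
                np.clip(
                    110.0 * truth.planted_simpson[roi_id] + rroi.normal(0.0, 5.0),
                    0.0,
                    100.0,
                )
            )
        nodal = "N0" if rroi.random() < 0.5 else "N+"
        records.append(
            ClinicalRecord(
                patient_id=patient_id,
                outcome=outcome,
                nodal=nodal,
                n_stage="N0" if nodal == "N0" else "N1",
                t_stage="T2",
                stage="IIA",
                grade="G2" if rroi.random() < 0.5 else "G3",
                er="pos" if rroi.random() < 0.5 else "neg",
                pr="neg",
                tils_percent=tils,
            )
        )

    return CohortDataset(rois, records), truth


def pooled_region_labels(
    original: CohortDataset, truth: SyntheticTruth, processed: CohortDataset
) -> np.ndarray:
    """True region labels for the processed cohort's retained pixels, pooled
    in the processed pixel order (outlier-dropped pixels are skipped via
    coordinate matching)."""
    out = []
    by_id = {r.roi_id: r for r in original.rois}
    for roi in processed.rois:
        orig = by_id[roi.roi_id]
        index = {tuple(c): i for i, c in enumerate(orig.coordinates)}
        idx = [index[tuple(c)] for c in roi.coordinates]
        out.extend(truth.region_labels[roi.roi_id][idx])
    return np.asarray(out)


def generate_peptide_library(
    truth: SyntheticTruth,
    decoy_fraction: float = 0.0,
    seed: Optional[int] = None,
    peptides_per_protein: Tuple[int, int] = (5, 10),
) -> List[PeptideEntry]:
    """Library with one entry per true peak plus decoys away from all peaks.

    True entries store the neutral monoisotopic mass consistent with the
    peak's m/z under the [M+H]+ convention.  Decoys are rejected within 0.2%
    (relative) of every true center so they can never match at the default
    0.05% tolerance.
    """
    if not (0 <= decoy_fraction < 1):
        raise ValueError("decoy_fraction must be in [0, 1)")
    if truth.n_peaks < 1:
        raise ValueError("truth has no peaks")
    rng = np.random.default_rng(1234 if seed is None else seed)

    entries: List[PeptideEntry] = []
    prot_idx = 0
    remaining = 0
    for p in range(truth.n_peaks):
        if remaining == 0:
            prot_idx += 1
            remaining = int(rng.integers(peptides_per_protein[0], peptides_per_protein[1] + 1))
        remaining -= 1
        entries.append(
            PeptideEntry(
                peptide_id=f"pep{p:04d}",
                sequence=f"SYNPEP{p:04d}K",
                neutral_mass=float(truth.peak_centers[p] - PROTON_MASS),
                protein_accession=f"SYNP{prot_idx:03d}",
                is_decoy=False,
            )
        )

    n_true = truth.n_peaks
    n_decoys = int(round(decoy_fraction * n_true / (1.0 - decoy_fraction)))
    lo = truth.peak_centers.min() - 50.0
    hi = truth.peak_centers.max() + 50.0
    made = 0
    while made < n_decoys:
        mz = rng.uniform(lo, hi)
        rel = np.abs(mz - truth.peak_centers) / truth.peak_centers
        if rel.min() < 2e-3:
            continue
        entries.append(
            PeptideEntry(
                peptide_id=f"decoy{made:04d}",
                sequence=f"DECOYPEP{made:04d}R",
                neutral_mass=float(mz - PROTON_MASS),
                protein_accession=f"DECP{made // 7:03d}",
                is_decoy=True,
            )
        )
        made += 1
    return entries
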