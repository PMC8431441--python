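"""Core domain types shared across the pipeline.

All heavy numeric payloads are plain numpy arrays; the dataclasses here add
validated structure on top, so every stage can rely on the same invariants
(sorted axes, unique pixel coordinates, metadata completeness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "MassAxis",
    "ROIDataset",
    "ClinicalRecord",
    "CohortDataset",
    "PreprocessingConfig",
    "ComponentsConfig",
    "DivikParams",
    "MetricsConfig",
    "StatsConfig",
    "AnnotationConfig",
    "PipelineConfig",
    "OUTCOMES",
    "NODAL",
    "N_STAGES",
    "T_STAGES",
    "STAGES",
    "GRADES",
    "RECEPTOR",
]

OUTCOMES = ("ND", "PD")
NODAL = ("N0", "N+")
N_STAGES = ("N0", "N1", "N2", "N3")
T_STAGES = ("T1c", "T2")
STAGES = ("IA", "IIA", "IIB", "IIIA", "IIIC")
GRADES = ("G2", "G3")
RECEPTOR = ("pos", "neg")


class MassAxis:
    """A strictly increasing m/z grid shared by all spectra of a cohort."""

    __slots__ = ("values",)

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("mass axis must be 1-D with at least 2 channels")
        if values.min() < 0:
            raise ValueError("mass axis values must be nonnegative")
        if not np.all(np.diff(values) > 0):
            raise ValueError("mass axis must be strictly increasing")
        self.values = values

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MassAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        v = self.values
        return f"MassAxis({v[0]:.2f}..{v[-1]:.2f}, C={v.size})"

    @property
    def spacing(self) -> float:
        """Median channel spacing in Da."""
        return float(np.median(np.diff(self.values)))

    @classmethod
    def linear(cls, start: float, stop: float, n_channels: int) -> "MassAxis":
        return cls(np.linspace(start, stop, n_channels))


class ROIDataset:
    """Pixel spectra of one cancer region of interest.

    ``intensities`` is a dense P x C matrix on a shared :class:`MassAxis`;
    ``coordinates`` holds 0-based integer (x, y) raster indices (physical
    pitch, nominally 100 um, never enters the math).
    """

    __slots__ = ("roi_id", "patient_id", "coordinates", "intensities", "axis")

    def __init__(self, roi_id, patient_id, coordinates, intensities, axis):
        coordinates = np.asarray(coordinates, dtype=np.int64)
        intensities = np.asarray(intensities, dtype=np.float64)
        if not isinstance(axis, MassAxis):
            axis = MassAxis(axis)
        if coordinates.ndim != 2 or coordinates.shape[1] != 2:
            raise ValueError("coordinates must be a P x 2 integer array")
        if intensities.ndim != 2:
            raise ValueError("intensities must be a P x C matrix")
        if intensities.shape[0] != coordinates.shape[0]:
            raise ValueError("coordinates and intensities disagree on pixel count")
        if intensities.shape[0] < 1:
            raise ValueError("ROI must contain at least one pixel")
        if intensities.shape[1] != len(axis):
            raise ValueError(
                f"intensity columns ({intensities.shape[1]}) do not match "
                f"axis length ({len(axis)})"
            )
        if intensities.min() < 0:
            raise ValueError("intensities must be nonnegative")
        uniq = np.unique(coordinates, axis=0)
        if uniq.shape[0] != coordinates.shape[0]:
            raise ValueError(f"duplicate pixel coordinates in ROI {roi_id!r}")
        self.roi_id = str(roi_id)
        self.patient_id = str(patient_id)
        self.coordinates = coordinates
        self.intensities = intensities
        self.axis = axis

    @property
    def n_pixels(self) -> int:
        return int(self.intensities.shape[0])

    def sorted_by_position(self) -> "ROIDataset":
        """Deterministic pixel order: ascending (y, x)."""
        order = np.lexsort((self.coordinates[:, 0], self.coordinates[:, 1]))
        return ROIDataset(
            self.roi_id,
            self.patient_id,
            self.coordinates[order],
            self.intensities[order],
            self.axis,
        )

    def __repr__(self) -> str:
        return f"ROIDataset({self.roi_id!r}, P={self.n_pixels}, C={len(self.axis)})"


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical metadata row."""

    patient_id: str
    outcome: str
    nodal: str
    n_stage: str
    t_stage: str
    stage: str
    grade: str
    er: str
    pr: str
    tils_percent: Optional[float] = None

    def __post_init__(self):
        checks = [
            ("outcome", OUTCOMES),
            ("nodal", NODAL),
            ("n_stage", N_STAGES),
            ("t_stage", T_STAGES),
            ("stage", STAGES),
            ("grade", GRADES),
            ("er", RECEPTOR),
            ("pr", RECEPTOR),
        ]
        for name, allowed in checks:
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(
                    f"invalid {name} value {value!r} for patient "
                    f"{self.patient_id!r}; allowed: {allowed}"
                )
        if (self.nodal == "N0") != (self.n_stage == "N0"):
            raise ValueError(
                f"nodal/n_stage inconsistency for patient {self.patient_id!r}: "
                f"nodal={self.nodal} n_stage={self.n_stage}"
            )
        if self.tils_percent is not None and not (0 <= self.tils_percent <= 100):
            raise ValueError(
                f"tils_percent out of [0, 100] for patient {self.patient_id!r}"
            )


class CohortDataset:
    """All ROIs of a study plus the clinical metadata table."""

    __slots__ = ("rois", "metadata")

    def __init__(self, rois, metadata):
        rois = list(rois)
        metadata = list(metadata)
        if not rois:
            raise ValueError("cohort must contain at least one ROI")
        axis = rois[0].axis
        by_patient = {}
        for rec in metadata:
            if rec.patient_id in by_patient:
                raise ValueError(f"duplicate patient_id {rec.patient_id!r}")
            by_patient[rec.patient_id] = rec
        seen = set()
        for roi in rois:
            if roi.axis != axis:
                raise ValueError(f"ROI {roi.roi_id!r} is not on the shared mass axis")
            if roi.patient_id not in by_patient:
                raise ValueError(
                    f"no clinical metadata for patient {roi.patient_id!r} "
                    f"(ROI {roi.roi_id!r})"
                )
            if roi.roi_id in seen:
                raise ValueError(f"duplicate roi_id {roi.roi_id!r}")
            seen.add(roi.roi_id)
        self.rois = sorted(rois, key=lambda r: r.roi_id)
        self.metadata = metadata

    @property
    def axis(self) -> MassAxis:
        return self.rois[0].axis

    @property
    def n_pixels(self) -> int:
        return sum(r.n_pixels for r in self.rois)

    def record_for(self, patient_id: str) -> ClinicalRecord:
        for rec in self.metadata:
            if rec.patient_id == patient_id:
                return rec
        raise KeyError(patient_id)

    def __repr__(self) -> str:
        return f"CohortDataset(n_rois={len(self.rois)}, P={self.n_pixels})"


# --------------------------------------------------------------------------
# Configuration blocks.  Every knob has a documented default so a pipeline
# run is fully specified by (config, seed); blocks serialize to plain YAML.
# --------------------------------------------------------------------------


@dataclass
class PreprocessingConfig:
    baseline_window: int = 50
    outlier_rule: str = "gmm"  # {"gmm", "mad"}
    mad_k: float = 3.0
    alignment_max_shift: int = 5
    tic_target: str = "dataset_median"  # {"dataset_median", "unity"}


@dataclass
class ComponentsConfig:
    min_valley_rel: float = 0.01
    max_components_per_fragment: int = 30
    amplitude_floor_rel: float = 0.01
    merge_sigma: float = 1.0
    em_max_iter: int = 300
    em_tol: float = 1e-8
    n_restarts: int = 2


@dataclass
class DivikParams:
    k_max: int = 10
    distance: str = "correlation"  # {"correlation", "euclidean"}
    feature_filter: str = "variance_gmm"  # {"variance_gmm", "amplitude_gmm", "none"}
    gap_reference_count: int = 10
    min_split_size: int = 200
    max_depth: int = 3
    n_init: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.gap_reference_count < 1:
            raise ValueError("gap_reference_count must be >= 1")
        if self.min_split_size <= self.k_max:
            raise ValueError("min_split_size must exceed k_max")


@dataclass
class MetricsConfig:
    similarity: str = "pearson"  # {"pearson", "cosine"}
    feature_space: str = "components"  # {"components", "channels"}
    max_pairs: int = 100_000
    simpson_estimator: str = "distinct_pairs"  # {"distinct_pairs", "plug_in"}


@dataclass
class StatsConfig:
    d_cluster_min: float = 0.5
    d_outcome_min: float = 0.2
    wilcoxon_mode: str = "auto"  # {"auto", "exact", "normal"}
    holm_adjust: bool = False


@dataclass
class AnnotationConfig:
    tolerance: float = 5e-4  # relative: +/-0.05%
    charge_convention: str = "MH_plus"  # {"MH_plus", "neutral"}


@dataclass
class PipelineConfig:
    """Bundle of per-stage parameter blocks plus the global seed."""

    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    components: ComponentsConfig = field(default_factory=ComponentsConfig)
    divik: DivikParams = field(default_factory=DivikParams)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        blocks = {
            "preprocessing": PreprocessingConfig,
            "components": ComponentsConfig,
            "divik": DivikParams,
            "metrics": MetricsConfig,
            "stats": StatsConfig,
            "annotation": AnnotationConfig,
        }
        for key, klass in blocks.items():
            if key in d and d[key] is not None:
                kwargs[key] = klass(**d[key])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
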