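import numpy as np
import pytest

from msiith.datatypes import ClinicalRecord, CohortDataset, MassAxis, ROIDataset


@pytest.fixture
def axis():
    return MassAxis.linear(600.0, 700.0, 201)


def make_roi(axis, intensities, roi_id="roiA", patient_id="p1"):
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    coords = np.column_stack([np.arange(n) % 10, np.arange(n) // 10])
    return ROIDataset(roi_id, patient_id, coords, intensities, axis)


def make_record(patient_id="p1", outcome="ND", **kw):
    defaults = dict(
        nodal="N0", n_stage="N0", t_stage="T2", stage="IIA",
        grade="G2", er="pos", pr="neg", tils_percent=None,
    )
    defaults.update(kw)
    return ClinicalRecord(patient_id=patient_id, outcome=outcome, **defaults)


@pytest.fixture
def tiny_cohort(axis):
    rng = np.random.default_rng(0)
    rois = []
    records = []
    for i, outcome in enumerate(["ND", "PD"]):
        I = rng.gamma(2.0, 5.0, size=(20, len(axis)))
        rois.append(make_roi(axis, I, roi_id=f"roi{i}", patient_id=f"p{i}"))
        records.append(make_record(patient_id=f"p{i}", outcome=outcome))
    return CohortDataset(rois, records)


@pytest.fixture(scope="session")
def desk_cohort():
    """One shared mid-scale synthetic cohort for the heavier integration
    tests (session-scoped to amortize generation cost)."""
    from msiith.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_patients_nd=3, n_patients_pd=3, roi_pixels=(150, 250),
        mz_start=600.0, mz_end=1100.0, n_channels=1250,
        n_peptide_peaks=60, min_peak_separation=5.0, sigma_range=(1.0, 1.8),
        regions_nd=(3, 3), regions_pd=(2, 2), n_region_archetypes=4,
        profile_effect=2.0, noise_sd=0.4, tic_cv=0.15,
        outlier_fraction=0.02, seed=1234,
    )
    return generate_cohort(cfg)
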