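import numpy as np
import pytest

from msiith.datatypes import MassAxis, PreprocessingConfig
from msiith.preprocess import (
    align_peaks,
    detect_outlier_spectra,
    estimate_baseline,
    mean_spectrum,
    normalize_tic,
    preprocess_cohort,
    subtract_baseline,
    unify_mass_axis,
)

from conftest import make_record, make_roi


CFG = PreprocessingConfig()


# ---------------------------------------------------------------- unify


def test_unify_identity(axis):
    roi = make_roi(axis, np.random.default_rng(0).random((5, len(axis))))
    out = unify_mass_axis(roi, axis)
    np.testing.assert_array_equal(out.intensities, roi.intensities)


def test_unify_linear_interpolation_closed_form():
    src = MassAxis([600.0, 602.0])
    roi = make_roi(src, np.array([[0.0, 2.0]]))
    target = MassAxis([600.0, 601.0, 602.0])
    out = unify_mass_axis(roi, target)
    assert out.intensities[0, 1] == pytest.approx(1.0)


def test_unify_no_extrapolation(axis):
    roi = make_roi(axis, np.ones((2, len(axis))))
    too_wide = MassAxis.linear(600.0, 3600.0, 50)
    with pytest.raises(ValueError, match="beyond"):
        unify_mass_axis(roi, too_wide)


# ---------------------------------------------------------------- baseline


def test_baseline_constant_fully_removed():
    spec = np.full(500, 5.0)
    out = subtract_baseline(spec, CFG)
    np.testing.assert_allclose(out, 0.0, atol=1e-6)


def test_baseline_keeps_peak_on_offset():
    x = np.arange(500, dtype=float)
    spec = 10.0 + 100.0 * np.exp(-0.5 * ((x - 250) / 3.0) ** 2)
    out = subtract_baseline(spec, CFG)
    apex = out[250]
    assert 85.0 <= apex <= 100.0


def test_baseline_zero_input():
    out = subtract_baseline(np.zeros(100), CFG)
    np.testing.assert_array_equal(out, 0.0)


def test_baseline_estimate_below_input():
    rng = np.random.default_rng(3)
    spec = rng.gamma(2.0, 3.0, size=400)
    base = estimate_baseline(spec, CFG.baseline_window)
    assert np.all(base <= spec + 1e-12)


# ---------------------------------------------------------------- outliers


def _tic_roi(axis, tics, rng=None):
    # spectra whose channel values are tic/C each (plus optional jitter)
    C = len(axis)
    I = np.tile(np.asarray(tics, float)[:, None] / C, (1, C))
    if rng is not None:
        I = I * (1 + 0.001 * rng.standard_normal(I.shape))
        I = np.clip(I, 0, None)
    return make_roi(axis, I)


def test_outliers_no_dispersion_both_rules(axis):
    roi = _tic_roi(axis, np.full(50, 1000.0))
    for rule in ("mad", "gmm"):
        cfg = PreprocessingConfig(outlier_rule=rule)
        assert not detect_outlier_spectra(roi, cfg).any()


def test_outliers_single_low_pixel_mad(axis):
    rng = np.random.default_rng(1)
    tics = np.full(1000, 1000.0) + rng.normal(0, 5, 1000)
    tics[123] = 10.0
    roi = _tic_roi(axis, tics)
    flags = detect_outlier_spectra(roi, PreprocessingConfig(outlier_rule="mad"))
    assert flags[123]
    assert flags.sum() <= 5  # only genuine extremes


def test_outliers_mad_closed_form():
    # direct check of the rule on a hand-computable sample
    from msiith.preprocess import _mad_flags

    x = np.log(np.array([100.0, 101, 99, 100, 102, 98, 100, 100, 1.0]))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    expect = np.abs(x - med) > 3 * 1.4826 * mad
    np.testing.assert_array_equal(_mad_flags(x, 3.0), expect)


def test_outliers_small_roi_error(axis):
    roi = _tic_roi(axis, np.full(5, 10.0))
    with pytest.raises(ValueError, match="mad"):
        detect_outlier_spectra(roi, CFG)


def test_outliers_gmm_recovers_planted_fraction():
    from msiith.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_patients_nd=1, n_patients_pd=1, roi_pixels=(800, 800),
        mz_start=600, mz_end=900, n_channels=750, n_peptide_peaks=40,
        min_peak_separation=5.0, sigma_range=(1.0, 1.8),
        regions_nd=(1, 1), regions_pd=(1, 1), outlier_fraction=0.03, seed=8,
    )
    cohort, truth = generate_cohort(cfg)
    roi = cohort.rois[0]
    flags = detect_outlier_spectra(roi, PreprocessingConfig(outlier_rule="gmm"))
    planted = truth.outlier_flags[roi.roi_id]
    n = planted.sum()
    # binomial-scale tolerance around the planted count
    assert abs(flags.sum() - n) <= max(3, 3 * np.sqrt(n))
    # the planted outliers (gain x0.01) are the ones flagged
    assert (flags & planted).sum() >= 0.9 * n


# ---------------------------------------------------------------- alignment


def test_align_identity_zero_shifts(axis):
    rng = np.random.default_rng(2)
    ref = rng.gamma(2.0, 3.0, size=len(axis))
    roi = make_roi(axis, np.tile(ref, (8, 1)))
    _, shifts = align_peaks(roi, CFG)
    np.testing.assert_array_equal(shifts, 0)


def test_align_recovers_planted_shift(axis):
    x = np.arange(len(axis), dtype=float)
    ref = 100.0 * np.exp(-0.5 * ((x - 100) / 2.5) ** 2)
    shifted = np.roll(ref, 2)  # spectrum moved +2 channels
    roi = make_roi(axis, np.vstack([np.tile(ref, (9, 1)), shifted[None, :]]))
    aligned, shifts = align_peaks(roi, CFG)
    assert shifts[-1] == -2
    np.testing.assert_array_equal(shifts[:-1], 0)
    np.testing.assert_allclose(aligned.intensities[-1][5:-5], ref[5:-5], atol=1e-9)


def test_align_planted_shifts_95pct_recovered():
    from msiith.synth import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_patients_nd=1, n_patients_pd=1, roi_pixels=(300, 300),
        mz_start=600, mz_end=900, n_channels=750, n_peptide_peaks=40,
        min_peak_separation=5.0, sigma_range=(1.0, 1.8),
        regions_nd=(1, 1), regions_pd=(1, 1), noise_sd=0.2, tic_cv=0.05,
        shift_channels=3, seed=17,
    )
    cohort, truth = generate_cohort(cfg)
    roi = cohort.rois[0]
    _, shifts = align_peaks(roi, CFG)
    planted = truth.pixel_shift[roi.roi_id]
    assert (shifts == -planted).mean() >= 0.95


def test_align_flat_spectra_shift_zero(axis):
    roi = make_roi(axis, np.zeros((12, len(axis))))
    _, shifts = align_peaks(roi, CFG)
    np.testing.assert_array_equal(shifts, 0)


# ---------------------------------------------------------------- TIC normalization


def test_normalize_to_dataset_median(axis):
    C = len(axis)
    I = np.vstack([np.full(C, t / C) for t in (50.0, 100.0, 200.0)])
    roi = make_roi(axis, I)
    out = normalize_tic(roi, CFG)  # per-ROI median = 100
    np.testing.assert_allclose(out.intensities.sum(axis=1), 100.0)


def test_normalize_preserves_proportions(axis):
    rng = np.random.default_rng(4)
    I = rng.gamma(2.0, 3.0, size=(5, len(axis)))
    roi = make_roi(axis, I)
    out = normalize_tic(roi, CFG, target=42.0)
    for before, after in zip(I, out.intensities):
        np.testing.assert_allclose(after / after.sum(), before / before.sum())


def test_normalize_idempotent(axis):
    rng = np.random.default_rng(5)
    roi = make_roi(axis, rng.gamma(2.0, 3.0, size=(5, len(axis))))
    once = normalize_tic(roi, CFG, target=100.0)
    twice = normalize_tic(once, CFG, target=100.0)
    np.testing.assert_allclose(once.intensities, twice.intensities)


def test_normalize_zero_tic_error(axis):
    I = np.ones((3, len(axis)))
    I[1] = 0.0
    roi = make_roi(axis, I)
    with pytest.raises(ValueError, match="zero-TIC"):
        normalize_tic(roi, CFG)


# ---------------------------------------------------------------- mean spectrum


def test_mean_spectrum_single_pixel(tiny_cohort, axis):
    from msiith.datatypes import CohortDataset

    roi = make_roi(axis, np.arange(len(axis), dtype=float)[None, :])
    cohort = CohortDataset([roi], [make_record()])
    np.testing.assert_array_equal(mean_spectrum(cohort), roi.intensities[0])


def test_mean_spectrum_arithmetic(axis):
    from msiith.datatypes import CohortDataset

    I = np.vstack([np.zeros(len(axis)), np.full(len(axis), 2.0)])
    cohort = CohortDataset([make_roi(axis, I)], [make_record()])
    np.testing.assert_allclose(mean_spectrum(cohort), 1.0)


def test_mean_spectrum_brute_force_oracle(axis):
    from msiith.datatypes import CohortDataset

    rng = np.random.default_rng(6)
    I = rng.gamma(2.0, 3.0, size=(100, len(axis)))
    cohort = CohortDataset([make_roi(axis, I)], [make_record()])
    # independent oracle: explicit sum / count per channel
    oracle = np.array([sum(I[i, c] for i in range(100)) / 100 for c in range(len(axis))])
    np.testing.assert_allclose(mean_spectrum(cohort), oracle, atol=1e-12)


def test_mean_spectrum_all_flagged_error(axis):
    from msiith.datatypes import CohortDataset

    cohort = CohortDataset([make_roi(axis, np.ones((3, len(axis))))], [make_record()])
    with pytest.raises(ValueError, match="no unflagged"):
        mean_spectrum(cohort, flags={"roiA": np.ones(3, dtype=bool)})


# ---------------------------------------------------------------- full chain


def test_preprocess_cohort_accounting_and_tic_cv(desk_cohort):
    cohort, truth = desk_cohort
    processed, report = preprocess_cohort(cohort)
    report.validate()
    for roi in cohort.rois:
        acc = report.per_roi[roi.roi_id]
        assert acc.n_input == roi.n_pixels
        assert acc.n_retained == acc.n_input - acc.n_flagged
    # planted gain removed: post-normalization TIC CV <= 1%
    for roi in processed.rois:
        tics = roi.intensities.sum(axis=1)
        assert tics.std() / tics.mean() <= 0.01


def test_preprocess_deterministic(desk_cohort):
    cohort, _ = desk_cohort
    p1, _ = preprocess_cohort(cohort)
    p2, _ = preprocess_cohort(cohort)
    for a, b in zip(p1.rois, p2.rois):
        np.testing.assert_array_equal(a.intensities, b.intensities)
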