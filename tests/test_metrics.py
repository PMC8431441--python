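import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiith.metrics import (
    pairwise_similarity,
    roi_size_cluster_correlation,
    simpson_index,
    HeterogeneityProfile,
)


# ---------------------------------------------------------------- similarity


def test_similarity_identical_pixels():
    rows = np.tile(np.random.default_rng(0).random(20), (5, 1))
    s = pairwise_similarity(rows)
    assert s.median_similarity == pytest.approx(1.0)
    assert s.n_pairs_evaluated == 10
    np.testing.assert_allclose(s.ecdf[:, 0], 1.0)


def test_similarity_known_pairwise_correlations():
    # a == b (corr 1); c correlates 0.5 with both => pair sims {1.0, 0.5, 0.5}
    rng = np.random.default_rng(1)
    a = rng.standard_normal(2000)
    noise = rng.standard_normal(2000)
    c = a + noise * np.sqrt(3)  # corr(a, c) = 1/2 exactly in expectation
    rows = np.vstack([a, a, c])
    s = pairwise_similarity(rows)
    assert s.median_similarity == pytest.approx(0.5, abs=0.05)


def test_similarity_median_exact_three_pixels():
    # deterministic construction: corr(a,b)=1, corr(a,c)=corr(b,c)=0.5
    a = np.array([1.0, -1.0, 1.0, -1.0])
    c = np.array([1.0, -1.0, -1.0, 1.0])  # corr(a, c) = 0.5? -> compute
    rows = np.vstack([a, a, np.array([1.0, 0.0, -1.0, 0.0])])
    s = pairwise_similarity(rows)
    sims = sorted(np.round(s.ecdf[:, 0], 12))
    assert sims[2] == pytest.approx(1.0)
    assert s.median_similarity == pytest.approx(sims[1])


def test_similarity_subsample_close_to_full():
    rng = np.random.default_rng(2)
    base = rng.random(30)
    rows = base + 0.3 * rng.standard_normal((200, 30))
    full = pairwise_similarity(rows, max_pairs=200 * 199 // 2)
    sub = pairwise_similarity(rows, max_pairs=1000, seed=3)
    assert sub.n_pairs_evaluated == 1000
    assert abs(sub.median_similarity - full.median_similarity) <= 0.02


def test_similarity_zero_variance_pixel_warns(caplog):
    rows = np.vstack([np.ones(10), np.arange(10, dtype=float)])
    with caplog.at_level("WARNING", logger="msiith"):
        s = pairwise_similarity(rows)
    assert s.median_similarity == 0.0


def test_similarity_requires_two_pixels():
    with pytest.raises(ValueError):
        pairwise_similarity(np.ones((1, 5)))


def test_similarity_scale_invariance():
    rng = np.random.default_rng(4)
    rows = rng.random((20, 15))
    s1 = pairwise_similarity(rows)
    s2 = pairwise_similarity(rows * 37.5)
    assert s1.median_similarity == pytest.approx(s2.median_similarity)


def test_similarity_ecdf_monotone_ends_at_one():
    rng = np.random.default_rng(5)
    s = pairwise_similarity(rng.random((30, 10)))
    assert np.all(np.diff(s.ecdf[:, 1]) >= 0)
    assert s.ecdf[-1, 1] == pytest.approx(1.0)
    assert np.all(np.abs(s.ecdf[:, 0]) <= 1.0)


# ---------------------------------------------------------------- Simpson


def simpson_pair_enumeration(labels):
    """Independent oracle: exhaustive enumeration of unordered pixel pairs."""
    labels = list(labels)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    discordant = sum(1 for i, j in pairs if labels[i] != labels[j])
    return discordant / len(pairs)


def test_simpson_single_cluster_zero():
    for n in (2, 5, 50):
        assert simpson_index(["x"] * n, "distinct_pairs") == 0.0
        assert simpson_index(["x"] * n, "plug_in") == 0.0


def test_simpson_counts_2_2():
    labels = ["a", "a", "b", "b"]
    assert simpson_index(labels) == pytest.approx(2.0 / 3.0)
    assert simpson_index(labels) == pytest.approx(simpson_pair_enumeration(labels))


def test_simpson_counts_3_1():
    labels = ["a", "a", "a", "b"]
    assert simpson_index(labels, "distinct_pairs") == pytest.approx(0.5)
    assert simpson_index(labels, "plug_in") == pytest.approx(0.375)
    assert simpson_pair_enumeration(labels) == pytest.approx(0.5)


def test_simpson_empty_error():
    with pytest.raises(ValueError):
        simpson_index([])


@given(
    st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=60)
)
@settings(max_examples=100, deadline=None)
def test_simpson_equals_pair_enumeration(labels):
    assert simpson_index(labels, "distinct_pairs") == pytest.approx(
        simpson_pair_enumeration(labels), abs=1e-12
    )


@given(st.lists(st.integers(min_value=0, max_value=4), min_size=2, max_size=40))
@settings(max_examples=50, deadline=None)
def test_simpson_label_rename_and_order_invariance(labels):
    d = simpson_index(labels)
    renamed = [chr(97 + l) for l in labels]
    assert simpson_index(renamed) == pytest.approx(d)
    shuffled = list(labels)
    np.random.default_rng(0).shuffle(shuffled)
    assert simpson_index(shuffled) == pytest.approx(d)


def test_simpson_plug_in_bounded():
    labels = [0] * 10 + [1] * 3 + [2]
    assert 0.0 <= simpson_index(labels, "plug_in") < 1.0
    assert 0.0 <= simpson_index(labels + [0], "plug_in") < 1.0


# ---------------------------------------------------------------- profiles


def make_profile(roi_id, n_pixels, k1, d1=0.5):
    return HeterogeneityProfile(
        roi_id=roi_id, n_pixels=n_pixels,
        cluster_counts={1: k1}, simpson={1: d1},
    )


def test_handbuilt_profile_simpson():
    labels = ["c1"] * 4 + ["c2"] * 3 + ["c3"] * 3
    assert simpson_index(labels) == pytest.approx(1 - (12 + 6 + 6) / 90)
    assert simpson_index(labels) == pytest.approx(0.73333, abs=1e-4)


def test_roi_profiles_integration(desk_cohort):
    from msiith.components import compute_feature_matrix, fit_gmm_components
    from msiith.divik import DivikParams, divik
    from msiith.metrics import roi_profiles
    from msiith.preprocess import mean_spectrum, preprocess_cohort

    cohort, _ = desk_cohort
    processed, _ = preprocess_cohort(cohort)
    comps = fit_gmm_components(mean_spectrum(processed), processed.axis, seed=0)
    fm = compute_feature_matrix(processed, comps)
    tree = divik(fm, DivikParams(max_depth=2, min_split_size=100, seed=0))
    profs = roi_profiles(processed, tree, fm)
    assert len(profs) == len(processed.rois)
    for p in profs:
        for lv in (1, 2):
            assert 1 <= p.cluster_counts[lv] <= p.n_pixels
            assert 0.0 <= p.simpson[lv] <= 1.0
            assert (p.simpson[lv] == 0.0) == (p.cluster_counts[lv] == 1)
        assert p.cluster_counts[2] >= p.cluster_counts[1]
        assert -1.0 <= p.similarity_median <= 1.0


# ---------------------------------------------------------------- size/K correlation


def test_correlation_strictly_increasing():
    profs = [make_profile(f"r{i}", 10 * (i + 1), i + 1) for i in range(5)]
    res = roi_size_cluster_correlation(profs, level=1)
    assert res.rho == pytest.approx(1.0)


def test_correlation_rank_arithmetic():
    profs = [make_profile("a", 10, 1), make_profile("b", 20, 3), make_profile("c", 30, 2)]
    res = roi_size_cluster_correlation(profs, level=1)
    assert res.rho == pytest.approx(0.5)


def test_correlation_constant_k_undefined():
    profs = [make_profile(f"r{i}", 10 * (i + 1), 2) for i in range(4)]
    res = roi_size_cluster_correlation(profs, level=1)
    assert not res.defined


def test_correlation_needs_three():
    with pytest.raises(ValueError):
        roi_size_cluster_correlation([make_profile("a", 5, 1), make_profile("b", 6, 2)], 1)


def test_correlation_null_simulation():
    rng = np.random.default_rng(6)
    insignificant = 0
    for _ in range(100):
        profs = [
            make_profile(f"r{i}", int(rng.integers(50, 500)), int(rng.integers(1, 8)))
            for i in range(30)
        ]
        res = roi_size_cluster_correlation(profs, level=1)
        if res.defined and res.p_value > 0.05:
            insignificant += 1
    assert insignificant >= 90
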