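import itertools

import numpy as np
import pytest
from scipy import stats as sps

from msiith.components import FeatureMatrix, SpectralComponent
from msiith.divik import LevelLabels
from msiith.stats import (
    classify_effect_size,
    cluster_contribution,
    cohens_d,
    conover_posthoc,
    contingency_2x2,
    correlate_tils,
    kruskal_wallis,
    pallant_r,
    screen_components,
    wilcoxon_rank_sum,
)

from conftest import make_record


# ---------------------------------------------------------------- Cohen's d


def test_cohens_d_identical_groups():
    g = [1.0, 2.0, 3.0]
    assert cohens_d(g, g) == 0.0
    assert classify_effect_size(0.0) == "negligible"


def test_cohens_d_closed_form():
    # s_pooled = sqrt(0.5), diff = -1 => d = -sqrt(2)
    assert cohens_d([0.0, 1.0], [1.0, 2.0]) == pytest.approx(-1.4142, abs=1e-4)


def test_cohens_d_one_pooled_sd_is_large():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 5000)
    sd = np.sqrt(((a.var(ddof=1)) + (a + 0).var(ddof=1)) / 2)
    b = a + sd
    d = cohens_d(b, a)
    assert d == pytest.approx(1.0, abs=1e-9)
    assert classify_effect_size(d) == "large"


def test_cohens_d_antisymmetric():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 20), rng.normal(0.4, 1.2, 30)
    assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))


def test_cohens_d_affine_invariance():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 20), rng.normal(0.4, 1.2, 30)
    assert cohens_d(3 * a + 7, 3 * b + 7) == pytest.approx(cohens_d(a, b))


def test_cohens_d_degenerate():
    assert cohens_d([5.0, 5.0], [5.0, 5.0]) == 0.0
    assert cohens_d([6.0, 6.0], [5.0, 5.0]) == np.inf
    assert cohens_d([4.0, 4.0], [5.0, 5.0]) == -np.inf


def test_cohens_d_size_guard():
    with pytest.raises(ValueError):
        cohens_d([1.0], [2.0, 3.0])


def test_effect_size_classes():
    assert classify_effect_size(0.19) == "negligible"
    assert classify_effect_size(0.2) == "small"
    assert classify_effect_size(-0.5) == "medium"
    assert classify_effect_size(0.81) == "large"


# ---------------------------------------------------------------- Wilcoxon


def exact_wilcoxon_oracle(a, b):
    """Brute-force permutation enumeration of the rank-sum distribution."""
    pooled = sorted(a + b)
    n1 = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    stats = [
        sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats)


def test_wilcoxon_exact_canonical():
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
    assert res.p_value == pytest.approx(0.1)
    assert exact_wilcoxon_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 13 - n1))
        vals = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
        a, b = list(vals[:n1]), list(vals[n1:])
        res = wilcoxon_rank_sum(a, b, mode="exact")
        assert res.p_value == pytest.approx(exact_wilcoxon_oracle(a, b), abs=1e-12)


def test_wilcoxon_identical_samples():
    res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0, abs=0.05)
    assert res.effect_size == pytest.approx(0.0, abs=0.1)


def test_wilcoxon_empty_group_error():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def test_wilcoxon_normal_mode_reasonable():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 50)
    b = rng.normal(2, 1, 50)
    res = wilcoxon_rank_sum(a, b, mode="normal")
    assert res.p_value < 1e-6
    assert res.effect_size > 0.5


def test_pallant_r_closed_form():
    assert pallant_r(2.0, 16) == pytest.approx(0.5)


# ---------------------------------------------------------------- Kruskal-Wallis


def test_kruskal_closed_form():
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(4.5714, abs=1e-4)


def test_kruskal_all_identical():
    res = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_eta_squared_closed_form():
    # eta^2 = (H - k + 1) / (N - k) = (7.5 - 1) / 18
    res = kruskal_wallis([[1, 2], [3, 4]])  # just to grab formula path
    eta = (7.5 - 2 + 1) / (20 - 2)
    assert eta == pytest.approx(0.3611, abs=1e-4)


def test_kruskal_monotone_transform_invariance():
    rng = np.random.default_rng(5)
    groups = [list(rng.normal(i, 1, 8)) for i in range(3)]
    h1 = kruskal_wallis(groups).statistic
    h2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups]).statistic
    assert h1 == pytest.approx(h2)


# ---------------------------------------------------------------- Conover


def test_conover_identical_groups_high_p():
    rng = np.random.default_rng(6)
    same = list(rng.normal(0, 1, 10))
    groups = [same, list(same), list(rng.normal(5, 1, 10)),
              list(rng.normal(-5, 1, 10))]
    results = conover_posthoc(groups)
    pair01 = next(r for r in results if r.extra["pair"] == (0, 1))
    assert pair01.p_value > 0.9


def test_conover_shifted_group_low_p():
    rng = np.random.default_rng(7)
    groups = [list(rng.normal(0, 1, 10)) for _ in range(3)]
    groups.append(list(rng.normal(10, 1, 10)))
    results = conover_posthoc(groups)
    for r in results:
        if 3 in r.extra["pair"]:
            assert r.p_value < 0.01
        else:
            assert r.p_value > 0.01


def conover_lsd_oracle(groups):
    """Independent route: Conover-Iman equals Fisher's LSD t-tests on the
    rank-transformed data, with the pooled residual variance from a one-way
    ANOVA on ranks."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    rg = [ranks[bounds[i]: bounds[i + 1]] for i in range(len(groups))]
    N, k = len(pooled), len(groups)
    grand = ranks.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in rg)
    sst = ((ranks - grand) ** 2).sum()
    mse = (sst - ssb) / (N - k)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1 / sizes[i] + 1 / sizes[j]))
            t = (rg[i].mean() - rg[j].mean()) / se
            out[(i, j)] = (t, 2 * sps.t.sf(abs(t), N - k))
    return out


def test_conover_matches_rank_lsd_oracle():
    rng = np.random.default_rng(8)
    groups = [list(rng.normal(i * 0.5, 1, 10)) for i in range(4)]
    results = conover_posthoc(groups)
    oracle = conover_lsd_oracle([np.array(g) for g in groups])
    for r in results:
        t_o, p_o = oracle[r.extra["pair"]]
        assert r.statistic == pytest.approx(t_o, abs=1e-6)
        assert r.p_value == pytest.approx(p_o, abs=1e-6)


def test_conover_needs_three_groups():
    with pytest.raises(ValueError):
        conover_posthoc([[1, 2], [3, 4]])


def test_conover_holm_adjustment_monotone():
    rng = np.random.default_rng(9)
    groups = [list(rng.normal(i, 1, 8)) for i in range(4)]
    results = conover_posthoc(groups, holm_adjust=True)
    for r in results:
        assert r.extra["p_holm"] >= r.p_value - 1e-12


# ---------------------------------------------------------------- screening


def make_fm(values, roi_ids=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    comps = [SpectralComponent(i, 600.0 + i, 1.0, 1.0, (i, i + 1)) for i in range(k)]
    if roi_ids is None:
        roi_ids = ["r0"] * n
    return FeatureMatrix(
        values=values, components=comps,
        roi_ids=np.array(roi_ids, dtype=object),
        coordinates=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]),
    )


def _screening_fixture():
    rng = np.random.default_rng(10)
    n = 200
    cluster = np.array(["c1"] * 100 + ["c2"] * 100)
    outcome = np.array((["ND"] * 50 + ["PD"] * 50) * 2, dtype=object)
    X = rng.normal(10, 1, size=(n, 4))
    X[cluster == "c1", 0] += 2.0   # cluster effect only
    X[outcome == "ND", 1] += 2.0   # outcome effect only
    X[cluster == "c1", 2] += 2.0   # both effects
    X[outcome == "ND", 2] += 1.0
    labels = LevelLabels(level=1, labels=cluster, k=2)
    return make_fm(X), labels, outcome


def test_screen_rule_application():
    fm, labels, outcome = _screening_fixture()
    res = screen_components(fm, labels, "c1", outcome)
    assert 2 in res.selected          # passes both thresholds
    assert 1 not in res.selected      # outcome-only
    assert 3 not in res.selected      # null feature
    assert abs(res.d_cluster[0]) >= 0.5 and abs(res.d_outcome[0]) < 0.2
    assert 0 not in res.selected      # cluster-only


def test_screen_monotone_in_thresholds():
    fm, labels, outcome = _screening_fixture()
    loose = set(screen_components(fm, labels, "c1", outcome, 0.3, 0.1).selected)
    tight = set(screen_components(fm, labels, "c1", outcome, 0.8, 0.5).selected)
    assert tight <= loose


def test_screen_small_cluster_error():
    fm, labels, outcome = _screening_fixture()
    with pytest.raises(ValueError):
        screen_components(fm, labels, "missing-cluster", outcome)


def test_screen_planted_modulated_peaks_recovered():
    rng = np.random.default_rng(11)
    n_half = 300
    cluster = np.array(["t"] * n_half + ["o"] * n_half)
    outcome = np.array((["ND"] * 150 + ["PD"] * 150) * 2, dtype=object)
    n_feat = 100
    X = rng.normal(20, 2, size=(2 * n_half, n_feat))
    planted = list(range(20))
    for f in planted:  # both region- and group-modulated
        X[cluster == "t", f] += 3.0
        X[outcome == "ND", f] += 1.5
    res = screen_components(make_fm(X), LevelLabels(1, cluster, 2), "t", outcome)
    hits = set(res.selected) & set(planted)
    false = set(res.selected) - set(planted)
    assert len(hits) >= 0.8 * len(planted)
    assert len(false) <= 0.1 * (n_feat - len(planted))


# ---------------------------------------------------------------- contributions


def test_cluster_contribution_fractions():
    roi_labels = {
        "full": np.array(["c1"] * 8),
        "partial": np.array(["c1"] * 3 + ["c2"] * 7),
        "none": np.array(["c2"] * 5),
    }
    outcome = {"full": "ND", "partial": "ND", "none": "PD"}
    fracs, test = cluster_contribution(roi_labels, "c1", outcome)
    assert fracs["full"] == 1.0
    assert fracs["partial"] == pytest.approx(0.3)
    assert fracs["none"] == 0.0
    assert test.group_sizes == (2, 1)


def test_cluster_contributions_sum_to_one():
    rng = np.random.default_rng(12)
    labels = rng.choice(["a", "b", "c"], size=100)
    roi_labels = {"r": labels}
    outcome = {"r": "ND"}
    total = 0.0
    for cl in "abc":
        fracs, _ = cluster_contribution(roi_labels, cl, {"r": "ND", **outcome})
        total += fracs["r"]
    assert total == pytest.approx(1.0)


# ---------------------------------------------------------------- TILs


from msiith.metrics import HeterogeneityProfile


def _tils_profiles(ds, tils, outcomes=None):
    profiles, records = [], []
    for i, (d, t) in enumerate(zip(ds, tils)):
        pid = f"p{i}"
        profiles.append(HeterogeneityProfile(pid, 100, {1: 2}, {1: d}))
        records.append(make_record(pid, outcome=(outcomes[i] if outcomes else "ND"),
                                   tils_percent=t))
    return profiles, records


def test_tils_exact_linear():
    ds = [0.1, 0.3, 0.5, 0.7]
    profiles, records = _tils_profiles(ds, [10 * d for d in ds])
    res = correlate_tils(profiles, records, level=1)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(10.0)


def test_tils_two_patients_error():
    profiles, records = _tils_profiles([0.1, 0.2], [1.0, 2.0])
    with pytest.raises(ValueError):
        correlate_tils(profiles, records, level=1)


def test_tils_constant_undefined():
    profiles, records = _tils_profiles([0.1, 0.3, 0.5], [5.0, 5.0, 5.0])
    res = correlate_tils(profiles, records, level=1)
    assert not res.defined


def test_tils_simulation_power():
    rng = np.random.default_rng(13)
    strong = 0
    for _ in range(100):
        ds = rng.uniform(0.2, 0.9, 33)
        tils = np.clip(50 * ds + rng.normal(0, 5, 33), 0, 100)
        profiles, records = _tils_profiles(ds, tils)
        res = correlate_tils(profiles, records, level=1)
        if res.r > 0.6:
            strong += 1
    assert strong >= 90


def test_tils_group_comparison():
    rng = np.random.default_rng(14)
    ds = rng.uniform(0.2, 0.8, 20)
    outcomes = ["ND"] * 10 + ["PD"] * 10
    tils = np.concatenate([rng.normal(40, 5, 10), rng.normal(20, 5, 10)])
    profiles, records = _tils_profiles(ds, tils, outcomes)
    res = correlate_tils(profiles, records, level=1)
    assert res.group_d > 0.8
    assert res.group_test.p_value < 0.01


# ---------------------------------------------------------------- utility


def test_contingency_utility():
    out = contingency_2x2([[20, 5], [8, 17]])
    assert out["p_fisher"] < 0.01
    assert out["p_chi2"] < 0.01
    sym = contingency_2x2([[10, 10], [10, 10]])
    assert sym["p_fisher"] == pytest.approx(1.0)
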