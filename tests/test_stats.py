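import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from voxconn import (GroupDesignTable, baseline_dependence, cluster_correct,
                     global_metric_tests, interaction_map, make_roi,
                     posthoc_paired_map)


@pytest.fixture(scope="module")
def roi60():
    return make_roi(60, "slab", seed=4)


def design_table(values):
    """values: dict (subject, session, time) -> metric value."""
    rows = [{"subject": s, "session": sess, "time": t, "threshold": 0.3,
             "K": v} for (s, sess, t), v in values.items()]
    return GroupDesignTable(table=pd.DataFrame(rows))


def test_design_table_must_be_crossed():
    rows = [{"subject": 0, "session": "sham", "time": "before", "K": 1.0},
            {"subject": 0, "session": "sham", "time": "after", "K": 1.0},
            {"subject": 1, "session": "sham", "time": "before", "K": 1.0}]
    with pytest.raises(ValueError):
        GroupDesignTable(table=pd.DataFrame(rows))


def test_global_tests_identical_and_degenerate():
    vals = {}
    for s in range(6):
        vals[(s, "sham", "before")] = 1.0 + s
        vals[(s, "sham", "after")] = 1.0 + s
    res = global_metric_tests(design_table(vals), "K")
    assert res["t"].iloc[0] == 0.0
    assert res["p"].iloc[0] == 1.0

    for s in range(6):
        vals[(s, "sham", "after")] = 1.5 + s      # constant nonzero shift
    with pytest.warns(UserWarning, match="zero-variance"):
        res2 = global_metric_tests(design_table(vals), "K")
    assert np.isnan(res2["t"].iloc[0])


def test_global_tests_match_scipy():
    rng = np.random.default_rng(0)
    before = rng.normal(size=10)
    after = before + rng.normal(size=10)
    vals = {}
    for s in range(10):
        vals[(s, "anodal", "before")] = before[s]
        vals[(s, "anodal", "after")] = after[s]
    res = global_metric_tests(design_table(vals), "K")
    t_ref, p_ref = sst.ttest_rel(after, before)
    assert res["t"].iloc[0] == pytest.approx(t_ref)
    assert res["p"].iloc[0] == pytest.approx(p_ref)


def test_interaction_f_zero_when_cells_equal():
    data = np.ones((8, 3, 2, 5)) + np.arange(8)[:, None, None, None]
    smap = interaction_map(data)
    assert np.allclose(smap.stat, 0.0, atol=1e-20)


def test_interaction_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM
    rng = np.random.default_rng(1)
    data = rng.normal(size=(8, 3, 2, 6))
    smap = interaction_map(data)
    for v in range(6):
        rows = []
        for s in range(8):
            for j, sess in enumerate("abc"):
                for t, time in enumerate(["x", "y"]):
                    rows.append({"subject": s, "session": sess, "time": time,
                                 "y": data[s, j, t, v]})
        res = AnovaRM(pd.DataFrame(rows), "y", "subject",
                      within=["session", "time"]).fit()
        f_ref = res.anova_table.loc["session:time", "F Value"]
        assert smap.stat[v] == pytest.approx(f_ref, rel=1e-8)
    assert smap.df == (2, 14)


def test_interaction_invariant_to_subject_offsets():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(6, 3, 2, 4))
    f1 = interaction_map(data).stat
    shifted = data + rng.normal(size=(6, 1, 1, 1))
    f2 = interaction_map(shifted).stat
    assert np.allclose(f1, f2, atol=1e-9)


def test_interaction_marks_missing_cells():
    data = np.random.default_rng(3).normal(size=(5, 3, 2, 4))
    data[2, 1, 0, 1] = np.nan
    smap = interaction_map(data)
    assert np.isnan(smap.stat[1])
    assert np.isfinite(smap.stat[0])


def test_posthoc_examples():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(8, 10))
    same = posthoc_paired_map(a, a.copy())
    assert np.allclose(same.stat, 0.0)
    b = rng.normal(size=(8, 10))
    smap = posthoc_paired_map(a, b)
    for v in rng.integers(0, 10, size=5):
        t_ref, p_ref = sst.ttest_rel(a[:, v], b[:, v])
        assert smap.stat[v] == pytest.approx(t_ref)
        assert smap.p[v] == pytest.approx(p_ref)


def test_cluster_correct_no_suprathreshold(roi60):
    rng = np.random.default_rng(5)
    diffs = rng.normal(size=(10, 60)) * 1e-3
    smap = posthoc_paired_map(diffs, np.zeros_like(diffs))
    smap.stat[:] = 0.0
    smap.p[:] = 1.0
    res = cluster_correct(smap, diffs, roi60, n_permutations=200, seed=0)
    assert res.clusters == []


def test_cluster_correct_uniform_effect(roi60):
    rng = np.random.default_rng(6)
    diffs = 1.0 + 0.05 * rng.normal(size=(12, 60))
    smap = posthoc_paired_map(diffs, np.zeros_like(diffs))
    res = cluster_correct(smap, diffs, roi60, n_permutations=500, seed=1)
    assert len(res.clusters) == 1
    assert res.clusters[0].size == 60
    assert res.clusters[0].size_mm3 == pytest.approx(60 * 27.0)
    # extent-based FWE cannot beat a full-extent null: p equals the chance
    # that a sign-flip pattern lights up the whole ROI, not arbitrarily small
    assert res.clusters[0].p_corrected <= 0.15


def test_cluster_correct_matches_exact_sign_flip_enumeration():
    """For a single-voxel map the Monte-Carlo corrected p must agree with
    exhaustive enumeration of all 2^n sign flips."""
    roi1 = make_roi(8, "blob", seed=0)
    rng = np.random.default_rng(7)
    n = 10
    d = rng.normal(size=n) + 1.2
    diffs = np.full((n, 8), np.nan)
    diffs[:, 0] = d
    smap = posthoc_paired_map(diffs, np.zeros_like(diffs))
    n_perm = 4000
    res = cluster_correct(smap, diffs, roi1, n_permutations=n_perm, seed=3)
    tcrit = sst.t.ppf(0.975, n - 1)
    count = 0
    for mask in range(2 ** n):
        signs = np.array([1 if mask >> k & 1 else -1 for k in range(n)])
        x = signs * d
        t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
        if abs(t) > tcrit:
            count += 1
    p_exact = count / 2 ** n
    # MC estimate of p within 4 standard errors of the exact value
    se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert len(res.clusters) == 1
    assert abs(res.clusters[0].p_corrected - p_exact) < 4 * se + 1 / n_perm


def test_cluster_correct_subject_relabeling(roi60):
    rng = np.random.default_rng(8)
    diffs = rng.normal(size=(12, 60)) + 0.4
    smap = posthoc_paired_map(diffs, np.zeros_like(diffs))
    res1 = cluster_correct(smap, diffs, roi60, n_permutations=2000, seed=4)
    perm = rng.permutation(12)
    smap2 = posthoc_paired_map(diffs[perm], np.zeros_like(diffs))
    res2 = cluster_correct(smap2, diffs[perm], roi60, n_permutations=2000,
                           seed=9)
    p1 = [c.p_corrected for c in res1.clusters[:2]]
    p2 = [c.p_corrected for c in res2.clusters[:2]]
    for a, b in zip(p1, p2):
        se = np.sqrt(max(a, 1e-3) / 2000)
        assert abs(a - b) < 5 * se + 0.02


def test_cluster_correct_interaction_mode(roi60):
    rng = np.random.default_rng(9)
    data = rng.normal(size=(8, 3, 2, 60))
    data[:, 0, 1, :10] += 2.0        # planted session-0 after-effect
    smap = interaction_map(data, roi=roi60)
    res = cluster_correct(smap, data, roi60, n_permutations=300, seed=5)
    assert all(c.sign == 1 for c in res.clusters)
    if res.significant():
        vox = set(res.significant()[0].voxels.tolist())
        assert vox & set(range(10))


def test_cluster_correct_warns_low_permutations(roi60):
    diffs = np.random.default_rng(10).normal(size=(8, 60))
    smap = posthoc_paired_map(diffs, np.zeros_like(diffs))
    with pytest.warns(UserWarning, match="permutations"):
        cluster_correct(smap, diffs, roi60, n_permutations=50, seed=0)


def test_baseline_dependence_perfect_and_formula():
    rng = np.random.default_rng(11)
    baseline = rng.random(10) + 1.0
    before = np.tile(baseline[:, None], (1, 6))
    after = before + 0.5 * before                 # effect exactly proportional
    res = baseline_dependence(np.arange(6), before, after)
    assert res["r2"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(0.5)

    effect = rng.normal(size=10)
    after2 = before + effect[:, None]
    res2 = baseline_dependence(np.arange(6), before, after2)
    ref = sst.linregress(baseline, effect)
    assert res2["slope"] == pytest.approx(ref.slope)
    assert res2["p"] == pytest.approx(ref.pvalue)


def test_baseline_dependence_requires_three_subjects():
    with pytest.raises(ValueError):
        baseline_dependence(np.arange(3), np.ones((2, 5)), np.ones((2, 5)))
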