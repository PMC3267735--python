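import numpy as np
import pytest

from voxconn import (EffectSpec, StudyDesign, correlation_matrix, make_roi,
                     preprocess_session, select_subregion, simulate_session,
                     simulate_study, default_study_design)
from voxconn.simulate import band_capacity, _band_limited_latents


def test_session_shapes_and_determinism(roi200):
    bold, nuis = simulate_session(roi200, n_timepoints=175, seed=3)
    assert bold.data.shape == (200, 175)
    assert nuis.regressors.shape == (9, 175)
    assert bold.tr_seconds == 1.8
    bold2, nuis2 = simulate_session(roi200, n_timepoints=175, seed=3)
    assert np.array_equal(bold.data, bold2.data)
    assert np.array_equal(nuis.regressors, nuis2.regressors)
    bold3, _ = simulate_session(roi200, n_timepoints=175, seed=4)
    assert not np.array_equal(bold.data, bold3.data)


def test_session_rejects_short_series(roi200):
    with pytest.raises(ValueError):
        simulate_session(roi200, n_timepoints=40)


def test_latents_are_band_limited_and_orthonormal():
    """Latent signals carry >95% spectral mass inside 0.005-0.12 Hz and are
    exactly orthonormal over the sample grid."""
    tr, T = 1.8, 175
    lat = _band_limited_latents(30, T, tr, np.random.default_rng(0))
    gram = lat.T @ lat / T
    assert np.allclose(gram, np.eye(30), atol=1e-10)
    freqs = np.fft.rfftfreq(T, d=tr)
    power = np.abs(np.fft.rfft(lat, axis=0)) ** 2
    inband = (freqs >= 0.005) & (freqs <= 0.12)
    frac = power[inband].sum() / power.sum()
    assert frac > 0.95


def test_band_capacity_bounds_latent_count():
    cap = band_capacity(175, 1.8)
    assert 40 <= cap <= 60
    with pytest.raises(ValueError):
        _band_limited_latents(cap + 1, 175, 1.8, np.random.default_rng(0))


def test_degenerate_no_noise_single_community():
    """With no noise, no nuisance coupling and one flat community profile,
    every pair of voxels is perfectly correlated."""
    roi = make_roi(20, "blob", seed=0)
    bold, _ = simulate_session(roi, noise_sd=0.0, nuisance_gain=0.0,
                               length_scale_vox=1e6, seed=5)
    r = np.corrcoef(bold.data)
    assert np.allclose(r, 1.0, atol=1e-8)


def test_local_coupling_raises_target_correlation(roi200):
    """Planted local coupling raises the mean within-target pairwise
    correlation of the preprocessed data by ~delta (0.15 +- 0.05)."""
    target = select_subregion(roi200, 40, seed=0)
    eff = EffectSpec(kind="local_coupling", target_voxels=tuple(target),
                     coupling_delta=0.15)
    deltas = []
    for seed in (3, 4, 5):
        r0 = correlation_matrix(preprocess_session(
            *simulate_session(roi200, seed=seed))).values
        r1 = correlation_matrix(preprocess_session(
            *simulate_session(roi200, eff, seed=seed))).values
        ii, jj = np.triu_indices(len(target), k=1)
        t = np.asarray(target)
        deltas.append(r1[t[ii], t[jj]].mean() - r0[t[ii], t[jj]].mean())
    assert 0.10 <= np.mean(deltas) <= 0.20


def test_effect_is_localized(roi200):
    """Voxels outside the target (and its shortcut partners) keep the null
    model: their synthetic time series are identical to the null run."""
    target = select_subregion(roi200, 40, seed=0)
    eff = EffectSpec(kind="local_coupling", target_voxels=tuple(target),
                     coupling_delta=0.15)
    b0, _ = simulate_session(roi200, seed=9)
    b1, _ = simulate_session(roi200, eff, seed=9)
    outside = np.setdiff1d(np.arange(200), np.asarray(target))
    assert np.allclose(b0.data[outside], b1.data[outside])
    assert not np.allclose(b0.data[np.asarray(target)],
                           b1.data[np.asarray(target)])


def test_effect_spec_validation():
    with pytest.raises(ValueError):
        EffectSpec(kind="wormhole")
    with pytest.raises(ValueError):
        EffectSpec(kind="none", coupling_delta=0.2)
    with pytest.raises(ValueError):
        EffectSpec(kind="local_coupling", coupling_delta=1.5)


def test_unreachable_delta_raises(roi200):
    target = select_subregion(roi200, 40, seed=0)
    eff = EffectSpec(kind="local_coupling", target_voxels=tuple(target),
                     coupling_delta=0.9)
    with pytest.raises(ValueError, match="unreachable"):
        simulate_session(roi200, eff, seed=1, effect_saturate=False)


def test_study_counts_and_determinism():
    design = default_study_design(n_subjects=2, seed=0)
    study = simulate_study(design, roi_params={"n_voxels": 60, "shape": "slab",
                                               "seed": 0},
                           session_params={"n_timepoints": 60})
    assert study.n_datasets == 2 * 3 * 2
    study2 = simulate_study(design, roi_params={"n_voxels": 60,
                                                "shape": "slab", "seed": 0},
                            session_params={"n_timepoints": 60})
    for r1, r2 in zip(study.records, study2.records):
        assert np.array_equal(r1.bold.data, r2.bold.data)

    small = StudyDesign(n_subjects=1, sessions=("sham",))
    s = simulate_study(small, roi_params={"n_voxels": 60, "shape": "slab",
                                          "seed": 0},
                       session_params={"n_timepoints": 60})
    assert s.n_datasets == 2


def test_study_null_cells_share_generator_parameters():
    """Sham and before cells are exchangeable: same architecture per subject,
    null effects everywhere, only session noise differs."""
    design = default_study_design(n_subjects=1, seed=5)
    study = simulate_study(design, roi_params={"n_voxels": 60, "shape": "slab",
                                               "seed": 5},
                           session_params={"n_timepoints": 60})
    for rec in study.records:
        if rec.time == "before" or rec.session == "sham":
            assert rec.effect.kind == "none" or rec.effect.coupling_delta == 0


def test_design_rejects_effect_in_sham_or_before():
    eff = EffectSpec(kind="local_coupling", target_voxels=(0,),
                     coupling_delta=0.1)
    with pytest.raises(ValueError):
        StudyDesign(effect_by_cell={("sham", "after"): eff})
    with pytest.raises(ValueError):
        StudyDesign(effect_by_cell={("anodal", "before"): eff})


def test_motion_qc_switch():
    roi = make_roi(30, "blob", seed=1)
    _, nuis = simulate_session(roi, seed=1, motion_rms=1.5)
    rms = np.sqrt(np.mean(nuis.motion**2, axis=1))
    assert rms.max() > 1.0
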