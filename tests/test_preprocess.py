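import numpy as np
import pytest

from voxconn import (BoldSeries, CleanSeries, NuisanceSet, bandpass,
                     discard_initial_volumes, motion_qc, nuisance_regression,
                     preprocess_session, prewhiten)
from oracles import normal_equations_residual


def _bold(data, tr=1.8):
    return BoldSeries(data=np.asarray(data, float), tr_seconds=tr)


def test_discard_initial_volumes():
    ts = _bold(np.random.default_rng(0).normal(size=(5, 175)))
    out = discard_initial_volumes(ts, 2)
    assert out.n_timepoints == 173
    assert np.array_equal(out.data, ts.data[:, 2:])
    assert discard_initial_volumes(ts, 0) is ts
    with pytest.raises(ValueError):
        discard_initial_volumes(ts, 180)


def test_motion_qc_rules():
    zeros = np.zeros((6, 100))
    ok, rms = motion_qc(zeros)
    assert ok and np.all(rms == 0)
    bad = zeros.copy()
    bad[1] = 1.2                      # constant 1.2 mm translation
    ok, rms = motion_qc(bad)
    assert not ok
    t = np.linspace(0, 4 * np.pi, 1000)
    sine = np.zeros((6, 1000))
    sine[0] = 0.5 * np.sin(t)
    ok, rms = motion_qc(sine)
    # rms of a sinusoid over whole periods = amplitude / sqrt(2)
    assert rms[0] == pytest.approx(0.5 / np.sqrt(2), rel=1e-3)
    with pytest.raises(ValueError):
        motion_qc(np.zeros((5, 10)))


def test_nuisance_regression_perfect_fit_and_orthogonality():
    rng = np.random.default_rng(1)
    nuis = NuisanceSet(rng.normal(size=(9, 120)))
    ts = _bold(np.vstack([nuis.regressors[8],         # equals global signal
                          rng.normal(size=(4, 120))]))
    clean = nuisance_regression(ts, nuis)
    assert np.allclose(clean.data[0], 0.0, atol=1e-9)
    assert np.allclose(clean.data.mean(axis=1), 0.0, atol=1e-10)
    for row in clean.data[1:]:
        for reg in nuis.regressors:
            r = np.corrcoef(row, reg)[0, 1]
            assert abs(r) < 1e-8


def test_nuisance_regression_zero_regressors_gives_demeaned():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(3, 80)) + 5.0
    with pytest.warns(UserWarning, match="collinear"):
        clean = nuisance_regression(_bold(x), NuisanceSet(np.zeros((9, 80))))
    assert np.allclose(clean.data, x - x.mean(axis=1, keepdims=True))
    assert len(clean.provenance["regressors_dropped"]) == 9


def test_nuisance_regression_matches_normal_equations():
    rng = np.random.default_rng(3)
    nuis = NuisanceSet(rng.normal(size=(9, 100)))
    ts = _bold(rng.normal(size=(6, 100)))
    clean = nuisance_regression(ts, nuis)
    X = np.column_stack([np.ones(100), nuis.regressors.T])
    for i in range(6):
        ref = normal_equations_residual(ts.data[i], X)
        assert np.allclose(clean.data[i], ref, atol=1e-8)


def lag1(x):
    xc = x - x.mean()
    return (xc[1:] * xc[:-1]).sum() / (xc**2).sum()


def test_prewhiten_white_noise_nearly_unchanged():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(4, 2000))
    out = prewhiten(CleanSeries(x, 1.8))
    for i in range(4):
        assert abs(lag1(out.data[i]) - lag1(x[i])) < 0.05


def test_prewhiten_removes_ar1_autocorrelation():
    rng = np.random.default_rng(5)
    eps = rng.normal(size=(3, 10000))
    x = np.zeros_like(eps)
    for t in range(1, 10000):
        x[:, t] = 0.5 * x[:, t - 1] + eps[:, t]
    out = prewhiten(CleanSeries(x, 1.8))
    for i in range(3):
        assert abs(lag1(out.data[i])) < 0.03


def test_prewhiten_constant_series_warns_zeros():
    x = np.vstack([np.ones(200), np.random.default_rng(6).normal(size=200)])
    with pytest.warns(UserWarning, match="constant"):
        out = prewhiten(CleanSeries(x, 1.8))
    assert np.allclose(out.data[0], 0.0)


def test_prewhiten_higher_order():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(2, 500))
    out = prewhiten(CleanSeries(x, 1.8), ar_order=2)
    assert out.data.shape == (2, 498)
    with pytest.raises(ValueError):
        prewhiten(CleanSeries(x[:, :15], 1.8), ar_order=2)


def _sine(freq_hz, tr=1.8, n=400):
    t = np.arange(n) * tr
    return np.sin(2 * np.pi * freq_hz * t)


def test_bandpass_passband_and_stopband():
    x = np.vstack([_sine(0.05), _sine(0.2), np.full(400, 3.0)])
    out = bandpass(CleanSeries(x, 1.8))
    mid = slice(50, 350)              # avoid filter edge effects
    assert np.std(out.data[0, mid]) == pytest.approx(np.std(x[0, mid]),
                                                     rel=0.1)
    assert np.std(out.data[1, mid]) < 0.1 * np.std(x[1, mid])
    assert np.max(np.abs(out.data[2, mid])) < 0.05


def test_bandpass_zero_phase():
    x = _sine(0.05)[None, :]
    out = bandpass(CleanSeries(x, 1.8))
    xc = np.correlate(out.data[0, 50:350], x[0, 50:350], mode="full")
    assert np.argmax(xc) == len(xc) // 2      # peak at lag 0


def test_bandpass_rejects_bad_band():
    x = np.random.default_rng(8).normal(size=(2, 100))
    with pytest.raises(ValueError):
        bandpass(CleanSeries(x, 1.8), low_hz=0.05, high_hz=0.5)
    with pytest.raises(ValueError):
        bandpass(CleanSeries(x, 1.8), low_hz=0.09, high_hz=0.01)


def test_chain_deterministic_with_provenance(roi200, null_session):
    bold, nuis, clean = null_session
    again = preprocess_session(bold, nuis)
    assert np.array_equal(clean.data, again.data)
    steps = clean.provenance["steps"]
    assert steps == ["nuisance_regression", "prewhiten(ar=1)",
                     "bandpass(0.01,0.09)"]
    assert clean.provenance["volumes_discarded"] == 2
    assert clean.provenance["order"] == "regress-prewhiten-bandpass"


def test_chain_alternative_order(null_session):
    bold, nuis, clean = null_session
    alt = preprocess_session(bold, nuis, order="prewhiten-regress-bandpass")
    assert alt.data.shape == clean.data.shape
    assert not np.allclose(alt.data, clean.data)


def test_chain_enforces_motion_qc(roi200):
    from voxconn import simulate_session
    bold, nuis = simulate_session(roi200, seed=1, motion_rms=1.5)
    with pytest.raises(ValueError, match="motion QC"):
        preprocess_session(bold, nuis)
    clean = preprocess_session(bold, nuis, enforce_qc=False)
    assert clean.n_timepoints == 172
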