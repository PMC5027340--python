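import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_extreme_slope
from epimap.errors import EmptyMapWarning, InvalidParameterError
from epimap.features import (
    ActivationMap,
    compute_ari,
    detect_activation_times,
    detect_repolarization_times,
    discrete_derivative,
)
from epimap.synthetic import Recording, make_geometry


def _recording_from_matrix(signal, fs_hz=25_000.0, stims=(0.0,), rows=None, cols=None):
    n_ch = signal.shape[0]
    if rows is None:
        rows, cols = 2, n_ch // 2
    geom = make_geometry(rows, cols, 1.0)
    return Recording(geometry=geom, sampling_rate_hz=fs_hz,
                     signal_mv=np.asarray(signal, dtype=np.float32),
                     stimulus_times_ms=tuple(stims))


def _gauss_deriv(t, center, sigma):
    u = (t - center) / sigma
    return u * np.exp(0.5 * (1 - u * u))


def _times(n_samples, fs_hz):
    return np.arange(n_samples) / (fs_hz / 1000.0)


class TestActivationDetection:
    def test_constructed_downstroke_at_50ms(self):
        t = _times(5000, 25_000.0)
        sig = np.tile(-4.0 * _gauss_deriv(t, 50.0, 1.0), (4, 1))
        rec = _recording_from_matrix(sig)
        am = detect_activation_times(rec, blanking_ms=5.0)
        np.testing.assert_allclose(am.time_ms, 50.0, atol=0.04)
        assert np.all(am.valid)
        assert np.all(am.slope_mv_per_ms < 0)

    def test_flat_zero_signal_invalid(self):
        sig = np.zeros((4, 2000))
        sig[0] = -4.0 * _gauss_deriv(_times(2000, 25_000.0), 40.0, 1.0)
        rec = _recording_from_matrix(sig)
        am = detect_activation_times(rec)
        assert am.valid[0]
        assert not am.valid[1:].any()
        assert np.isnan(am.time_ms[1:]).all()

    def test_random_noise_equals_brute_force(self, rng):
        sig = rng.normal(size=(6, 1500))
        rec = _recording_from_matrix(sig, rows=2, cols=3)
        am = detect_activation_times(rec, blanking_ms=1.0,
                                     min_slope_mv_per_ms=0.0)
        fs_khz = rec.sampling_rate_hz / 1000.0
        i0 = int(np.ceil(1.0 * fs_khz))
        for ch in range(6):
            i, slope = brute_force_extreme_slope(sig[ch].astype(np.float32),
                                                 rec.sampling_rate_hz,
                                                 i0, 1498, "min")
            assert am.time_ms[ch] == pytest.approx(i / fs_khz, abs=1e-9)
            assert am.slope_mv_per_ms[ch] == pytest.approx(slope, rel=1e-6)

    def test_bad_channels_invalid(self):
        t = _times(3000, 25_000.0)
        sig = np.tile(-4.0 * _gauss_deriv(t, 50.0, 1.0), (4, 1))
        rec = _recording_from_matrix(sig)
        rec = Recording(geometry=rec.geometry.with_bad_channels([2]),
                        sampling_rate_hz=rec.sampling_rate_hz,
                        signal_mv=rec.signal_mv, stimulus_times_ms=(0.0,))
        am = detect_activation_times(rec)
        assert not am.valid[2]
        assert am.valid[[0, 1, 3]].all()

    def test_empty_window_raises(self, noiseless_recording):
        with pytest.raises(InvalidParameterError):
            detect_activation_times(noiseless_recording, search_window_ms=(50.0, 50.0))
        with pytest.raises(InvalidParameterError):
            detect_activation_times(noiseless_recording, search_window_ms=(2.0, 4.0),
                                    blanking_ms=5.0)

    def test_all_invalid_warns(self):
        rec = _recording_from_matrix(np.zeros((4, 2000)))
        with pytest.warns(EmptyMapWarning):
            am = detect_activation_times(rec)
        assert am.n_valid == 0

    def test_stimulus_index_bounds(self, noiseless_recording):
        with pytest.raises(InvalidParameterError):
            detect_activation_times(noiseless_recording, stimulus_index=5)

    def test_time_shift_equivariance(self, rng):
        """Shifting the whole signal by k samples shifts times by exactly
        k sample periods."""
        base = rng.normal(size=(4, 2000))
        k = 250
        shifted = np.roll(base, k, axis=1)
        fs = 25_000.0
        am0 = detect_activation_times(_recording_from_matrix(base, fs),
                                      search_window_ms=(10.0, 40.0),
                                      min_slope_mv_per_ms=0.0)
        am1 = detect_activation_times(_recording_from_matrix(shifted, fs),
                                      search_window_ms=(10.0 + k / 25.0,
                                                        40.0 + k / 25.0),
                                      min_slope_mv_per_ms=0.0)
        np.testing.assert_allclose(am1.time_ms - am0.time_ms, k / 25.0, atol=1e-9)


class TestRepolarizationDetection:
    def _beat(self, act_ms=50.0, ari_ms=200.0, n=4, n_samples=12000):
        t = _times(n_samples, 25_000.0)
        row = (-4.0 * _gauss_deriv(t, act_ms, 1.0)
               + 1.5 * _gauss_deriv(t, act_ms + ari_ms, 12.0))
        return _recording_from_matrix(np.tile(row, (n, 1)))

    def test_programmed_upslope_detected(self):
        rec = self._beat(ari_ms=200.0)
        am = detect_activation_times(rec)
        rm = detect_repolarization_times(rec, am, repol_window_ms=(80.0, 400.0))
        np.testing.assert_allclose(rm.time_ms - am.time_ms, 200.0, atol=0.08)
        assert np.all(rm.valid)
        assert np.all(rm.slope_mv_per_ms > 0)

    def test_invalid_activation_propagates(self):
        rec = self._beat()
        am = detect_activation_times(rec)
        am = ActivationMap(channel_id=am.channel_id, time_ms=am.time_ms,
                           slope_mv_per_ms=am.slope_mv_per_ms,
                           valid=np.array([True, False, True, True]),
                           stimulus_time_ms=am.stimulus_time_ms)
        rm = detect_repolarization_times(rec, am)
        assert not rm.valid[1]
        assert np.isnan(rm.time_ms[1])

    def test_noisy_beat_equals_brute_force(self, rng):
        rec = self._beat(ari_ms=200.0)
        noisy = rec.signal_mv + rng.normal(0, 0.05, rec.signal_mv.shape).astype(np.float32)
        rec = _recording_from_matrix(noisy)
        am = detect_activation_times(rec)
        rm = detect_repolarization_times(rec, am, repol_window_ms=(80.0, 400.0))
        fs_khz = 25.0
        for ch in range(4):
            act_abs = am.time_ms[ch]
            i0 = max(int(np.ceil((act_abs + 80.0) * fs_khz)), 1)
            i1 = min(int(np.floor((act_abs + 400.0) * fs_khz)), rec.n_samples - 2)
            i, _ = brute_force_extreme_slope(rec.signal_mv[ch],
                                             rec.sampling_rate_hz, i0, i1, "max")
            assert rm.time_ms[ch] == pytest.approx(i / fs_khz, abs=1e-9)

    def test_window_order_enforced(self):
        rec = self._beat()
        am = detect_activation_times(rec)
        with pytest.raises(InvalidParameterError):
            detect_repolarization_times(rec, am, repol_window_ms=(400.0, 80.0))


class TestARI:
    def _maps(self, act, repol, valid_act=None, valid_rep=None):
        n = len(act)
        act = np.asarray(act, float)
        repol = np.asarray(repol, float)
        va = np.ones(n, bool) if valid_act is None else np.asarray(valid_act)
        vr = np.ones(n, bool) if valid_rep is None else np.asarray(valid_rep)
        am = ActivationMap.from_times(act, valid=va)
        from epimap.features import RepolarizationMap
        rm = RepolarizationMap(channel_id=np.arange(n), time_ms=repol,
                               slope_mv_per_ms=np.full(n, np.nan), valid=vr)
        return am, rm

    def test_simple_subtraction(self):
        am, rm = self._maps([50.0, 60.0], [250.0, 240.0])
        ari = compute_ari(am, rm)
        np.testing.assert_allclose(ari.ari_ms, [200.0, 180.0])
        assert ari.mean_ms == pytest.approx(190.0)

    def test_ordering_violation_flagged(self):
        am, rm = self._maps([50.0, 50.0], [40.0, 250.0])
        ari = compute_ari(am, rm)
        assert not ari.valid[0]
        assert ari.valid[1]
        assert np.isnan(ari.ari_ms[0])

    def test_recovery_on_synthetic_recording(self, planar_truth):
        from epimap.synthetic import synthesize_recording
        rec = synthesize_recording(planar_truth, ari_ms=180.0, noise_sd_mv=0.0,
                                   duration_s=0.6, stimulus_times_ms=(0.0,))
        am = detect_activation_times(rec)
        rm = detect_repolarization_times(rec, am)
        ari = compute_ari(am, rm)
        assert ari.mean_ms == pytest.approx(180.0, abs=1.0)
        assert ari.n_valid == 128

    def test_size_mismatch(self):
        am, _ = self._maps([50.0, 60.0], [250.0, 240.0])
        _, rm = self._maps([50.0], [250.0])
        with pytest.raises(InvalidParameterError):
            compute_ari(am, rm)


@settings(max_examples=40, deadline=None)
@given(data=st.data())
def test_detector_oracle_property(data):
    """Both detectors equal an exhaustive discrete-derivative scan on
    arbitrary random signals (property form of the oracle check)."""
    n_samples = data.draw(st.integers(200, 600))
    seed = data.draw(st.integers(0, 2 ** 31))
    rng = np.random.default_rng(seed)
    sig4 = rng.normal(size=(4, n_samples))
    rec = _recording_from_matrix(sig4, fs_hz=1000.0, rows=2, cols=2)
    am = detect_activation_times(rec, blanking_ms=2.0, min_slope_mv_per_ms=0.0)
    fs_khz = 1.0
    i0 = int(np.ceil(2.0 * fs_khz))
    for ch in range(4):
        i, _ = brute_force_extreme_slope(rec.signal_mv[ch], 1000.0, i0,
                                         n_samples - 2, "min")
        assert am.time_ms[ch] == pytest.approx(i / fs_khz, abs=1e-9)


def test_discrete_derivative_definition():
    x = np.array([[0.0, 1.0, 4.0, 9.0, 16.0]])
    d = discrete_derivative(x, 1000.0)  # dt = 1 ms
    np.testing.assert_allclose(d[0, 1:-1], [2.0, 4.0, 6.0])
    assert np.isnan(d[0, 0]) and np.isnan(d[0, -1])
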