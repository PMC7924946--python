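"""Time-frequency decomposition and z-baseline normalization."""

import numpy as np
import pytest

from cuedpain.design import ConditionCell
from cuedpain.preprocess import EpochSet
from cuedpain.tfr import (
    TFR,
    BaselineSpec,
    average_by_condition,
    tfr_hanning,
    tfr_multitaper,
    zbaseline,
)


def make_epochs(data, sfreq=500.0, t0=-1.0, lock="cue"):
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[None, None, :]
    n_tr, n_ch, n_s = data.shape
    return EpochSet(
        data=data, times=t0 + np.arange(n_s) / sfreq, sfreq=sfreq,
        ch_names=[f"ch{i}" for i in range(n_ch)], conditions=[None] * n_tr,
        lock=lock, reference="common_average",
    )


def sinusoid(freq, sfreq=500.0, duration=2.0, amp=1.0):
    t = np.arange(int(duration * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t)


class TestHanning:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        tfr = tfr_hanning(make_epochs(sinusoid(10.0)))
        peak_bins = tfr.power[0, 0].argmax(axis=0)
        assert (tfr.freqs[peak_bins] == 10.0).all()

    def test_amplitude_doubling_quadruples_power(self):
        a = tfr_hanning(make_epochs(sinusoid(10.0)))
        b = tfr_hanning(make_epochs(sinusoid(10.0, amp=2.0)))
        i = list(a.freqs).index(10.0)
        np.testing.assert_allclose(b.power[0, 0, i], 4.0 * a.power[0, 0, i], rtol=1e-5)

    def test_white_noise_spectrum_flat_within_ten_percent(self):
        rng = np.random.default_rng(0)
        tfr = tfr_hanning(make_epochs(rng.standard_normal((200, 1, 1000))))
        mean = tfr.power.mean(axis=(0, 1, 3))
        sel = (tfr.freqs >= 5) & (tfr.freqs <= 25)
        assert np.abs(mean[sel] / mean[sel].mean() - 1).max() < 0.10

    def test_raw_power_nonnegative_and_grid_metadata(self):
        tfr = tfr_hanning(make_epochs(sinusoid(10.0)))
        assert (tfr.power >= 0).all()
        assert tfr.baseline_state == "raw"
        np.testing.assert_array_equal(tfr.freqs, np.arange(1.0, 31.0))
        np.testing.assert_allclose(np.diff(tfr.times), 0.05)

    def test_times_without_window_support_rejected(self):
        ep = make_epochs(sinusoid(10.0))
        with pytest.raises(ValueError, match="window support"):
            tfr_hanning(ep, times=np.array([ep.times[0] + 0.05]))


class TestMultitaper:
    def test_taper_count_follows_slepian_convention(self):
        # K = 2*T*W - 1 = 2 * 0.2 s * 15 Hz - 1 = 5
        tfr = tfr_multitaper(make_epochs(sinusoid(70.0)))
        assert tfr.estimator["n_tapers"] == 5

    def test_half_power_width_matches_smoothing_bandwidth(self):
        tfr = tfr_multitaper(make_epochs(sinusoid(70.0)), times=np.array([0.0]))
        spec = tfr.power[0, 0, :, 0]
        above = tfr.freqs[spec >= spec.max() / 2]
        width = above.max() - above.min()
        assert 22.0 <= width <= 38.0  # ~2W = 30 Hz

    def test_zero_signal_gives_zero_power(self):
        tfr = tfr_multitaper(make_epochs(np.zeros((1, 1, 1000))))
        np.testing.assert_array_equal(tfr.power, 0.0)

    def test_too_few_tapers_rejected(self):
        with pytest.raises(ValueError, match="taper"):
            tfr_multitaper(make_epochs(sinusoid(70.0)), smoothing=2.0)

    def test_amplitude_doubling_quadruples_power(self):
        a = tfr_multitaper(make_epochs(sinusoid(70.0)))
        b = tfr_multitaper(make_epochs(sinusoid(70.0, amp=2.0)))
        i = list(a.freqs).index(70.0)
        np.testing.assert_allclose(b.power[0, 0, i], 4.0 * a.power[0, 0, i], rtol=1e-5)

    def test_matches_independent_multitaper_estimate(self):
        # mne's multitaper PSD as an independent oracle on one segment
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        sfreq = 500.0
        x = rng.standard_normal(int(2.0 * sfreq))
        tfr = tfr_multitaper(make_epochs(x[None, None, :]), times=np.array([0.0]),
                             freqs=np.arange(35.0, 101.0, 5.0), pad_seconds=0.2)
        seg = x[int(0.9 * sfreq) : int(0.9 * sfreq) + 100]
        psd, freqs = mne.time_frequency.psd_array_multitaper(
            seg, sfreq, bandwidth=30.0, adaptive=False, normalization="full",
            verbose="error")
        ours = tfr.power[0, 0, :, 0]
        sel = np.isin(freqs, tfr.freqs)
        ratio = ours / psd[sel]
        assert ratio.std() / ratio.mean() < 0.05  # equal up to a constant scale


class TestZBaseline:
    def _tfr(self, power, times=None, freqs=None):
        power = np.asarray(power, float)
        times = np.arange(power.shape[-1]) * 0.05 - 1.0 if times is None else times
        freqs = np.arange(1.0, power.shape[2] + 1) if freqs is None else freqs
        return TFR(power=power, freqs=freqs, times=times,
                   ch_names=[f"ch{i}" for i in range(power.shape[1])],
                   estimator={"method": "test"})

    def test_arithmetic_example(self):
        # mu=10, sd=2 over the baseline, P=14 afterwards -> z=2
        power = np.full((1, 1, 1, 10), 10.0)
        power[..., 1::2] = 8.0
        power[..., 0::2] = 12.0  # mean 10, sd 2
        power[..., -1] = 14.0
        power[..., -2] = 10.0
        tfr = self._tfr(power)
        out = zbaseline(tfr, BaselineSpec((-1.0, -0.65)))  # first 8 points
        base = power[..., :8]
        mu, sd = base.mean(), base.std()
        assert out.power[0, 0, 0, -1] == pytest.approx((14.0 - mu) / sd, rel=1e-6)

    def test_constant_baseline_level_raises_degenerate(self):
        power = np.full((1, 1, 1, 10), 7.0)
        with pytest.raises(ValueError, match="zero baseline standard deviation"):
            zbaseline(self._tfr(power), BaselineSpec((-1.0, -0.7)))

    def test_baseline_window_z_has_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        power = rng.gamma(2.0, size=(5, 3, 4, 40))
        out = zbaseline(self._tfr(power), BaselineSpec((-1.0, -0.55)))
        sel = (out.times >= -1.0) & (out.times <= -0.55)
        base = out.power[..., sel]
        np.testing.assert_allclose(base.mean(axis=(0, -1)), 0.0, atol=1e-6)
        np.testing.assert_allclose(base.std(axis=(0, -1)), 1.0, rtol=1e-5)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        power = rng.gamma(2.0, size=(2, 2, 3, 30))
        scale = rng.uniform(0.5, 3.0, size=(1, 2, 3, 1))
        spec = BaselineSpec((-1.0, -0.6))
        a = zbaseline(self._tfr(power), spec)
        b = zbaseline(self._tfr(power * scale), spec)
        np.testing.assert_allclose(a.power, b.power, rtol=1e-4)

    def test_double_normalization_rejected(self):
        rng = np.random.default_rng(2)
        out = zbaseline(self._tfr(rng.gamma(2.0, size=(1, 1, 1, 30))),
                        BaselineSpec((-1.0, -0.6)))
        with pytest.raises(ValueError, match="already"):
            zbaseline(out, BaselineSpec((-1.0, -0.6)))

    def test_default_windows_per_lock_mode(self):
        assert BaselineSpec.default_for("cue").window == (-0.650, -0.150)
        assert BaselineSpec.default_for("stimulus").window == (-2.950, -2.450)


class TestConditionAveraging:
    def test_average_by_condition_means_per_cell(self):
        rng = np.random.default_rng(0)
        cells = [ConditionCell(stimulus_level=s, cue_level=0) for s in (-1, 1)]
        conditions = [cells[0], cells[1], cells[0], cells[1], cells[0]]
        ep = make_epochs(rng.standard_normal((5, 2, 500)))
        ep = ep.copy(conditions=conditions)
        tfr = tfr_hanning(ep, freqs=np.arange(5.0, 10.0))
        avg = average_by_condition(tfr, cells)
        assert avg.power.shape[0] == 2
        np.testing.assert_allclose(
            avg.power[0], tfr.power[[0, 2, 4]].mean(axis=0), rtol=1e-6)

    def test_empty_cell_rejected(self):
        cells = [ConditionCell(stimulus_level=-1, cue_level=0),
                 ConditionCell(stimulus_level=1, cue_level=1)]
        ep = make_epochs(np.random.default_rng(0).standard_normal((2, 1, 500)))
        ep = ep.copy(conditions=[cells[0], cells[0]])
        tfr = tfr_hanning(ep, freqs=np.arange(5.0, 8.0))
        with pytest.raises(ValueError, match="no trials"):
            average_by_condition(tfr, cells)


def test_temporal_smearing_bounded_by_window_length():
    # a 200 ms burst of band power must not push supra-half-max responses
    # further than one window length from the burst edges
    sfreq = 500.0
    t = np.arange(int(3.0 * sfreq)) / sfreq - 1.5
    x = np.sin(2 * np.pi * 10 * t) * ((t >= 0.0) & (t <= 0.2))
    tfr = tfr_hanning(make_epochs(x[None, None, :], t0=-1.5))
    i = list(tfr.freqs).index(10.0)
    resp = tfr.power[0, 0, i]
    above = tfr.times[resp >= resp.max() / 2]
    assert above.min() >= 0.0 - 0.3
    assert above.max() <= 0.2 + 0.3
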