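import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelvimag.epochs import Epoch
from pelvimag.features import (
    PSDResult,
    epoch_features,
    power_map,
    rpsd_bands,
    sliding_rms,
    smooth_ma,
    total_power,
    welch_psd,
)
from pelvimag.io_core import ChannelInfo, ChannelRole, ExerciseLabel
from pelvimag.synthetic import (
    BurstSpec,
    SessionSpec,
    simulate_session,
)

FS = 1200.0


def brute_force_sliding_rms(x, win, hop):
    out = []
    for start in range(0, len(x) - win + 1, hop):
        seg = x[start : start + win]
        out.append(np.sqrt(np.mean(seg**2)))
    return np.array(out)


def brute_force_moving_average(x, n):
    half_lo = n // 2
    half_hi = n - half_lo
    out = []
    for i in range(len(x)):
        lo, hi = max(i - half_lo, 0), min(i + half_hi, len(x))
        out.append(np.mean(x[lo:hi]))
    return np.array(out)


class TestSlidingRms:
    def test_constant_signal(self):
        out = sliding_rms(np.full(2400, -3.0), FS)
        np.testing.assert_allclose(out, 3.0)

    def test_unit_sinusoid_is_inverse_sqrt2(self):
        # 100 Hz: each 240-sample window spans exactly 20 cycles
        t = np.arange(4800) / FS
        out = sliding_rms(np.sin(2 * np.pi * 100 * t), FS)
        np.testing.assert_allclose(out, 1 / np.sqrt(2), atol=1e-3)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal(1200)
        out = sliding_rms(x, FS)
        oracle = brute_force_sliding_rms(x, win=240, hop=1)
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sliding_rms(np.zeros(100), FS)


class TestSmoothMa:
    def test_constant_series_unchanged(self):
        out = smooth_ma(np.full(500, 2.5), 100)
        np.testing.assert_allclose(out, 2.5)

    def test_alternating_series_cancels_in_interior(self):
        x = np.tile([1.0, -1.0], 250)
        out = smooth_ma(x, 100)
        np.testing.assert_allclose(out[100:-100], 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal(777)
        np.testing.assert_allclose(
            smooth_ma(x, 100), brute_force_moving_average(x, 100), atol=1e-12
        )

    def test_output_length_preserved(self, rng):
        x = rng.standard_normal(50)  # shorter than the smoothing window
        assert len(smooth_ma(x, 100)) == 50


class TestWelchPsd:
    def test_white_noise_total_power_parseval(self, rng):
        sigma = 2.0
        x = sigma * rng.standard_normal(int(60 * FS))
        psd = welch_psd(x, FS)
        df = psd.freqs[1] - psd.freqs[0]
        assert np.sum(psd.density) * df == pytest.approx(sigma**2, rel=0.10)

    def test_sinusoid_peak_location(self):
        t = np.arange(int(10 * FS)) / FS
        psd = welch_psd(np.sin(2 * np.pi * 100 * t), FS)
        assert psd.freqs[np.argmax(psd.density)] == pytest.approx(100.0, abs=0.51)

    def test_one_second_window_gives_1hz_resolution(self, rng):
        psd = welch_psd(rng.standard_normal(int(5 * FS)), FS)
        assert psd.freqs[1] - psd.freqs[0] == pytest.approx(1.0)

    def test_zero_signal_zero_density(self):
        psd = welch_psd(np.zeros(int(5 * FS)), FS)
        np.testing.assert_array_equal(psd.density, 0.0)


class TestBandPowers:
    def _flat_psd(self):
        freqs = np.arange(0.0, 601.0)
        return PSDResult(freqs=freqs, density=np.ones_like(freqs), window_s=1.0, overlap=0.5)

    def test_unit_density_band_sum_counts_bins(self):
        assert total_power(self._flat_psd()) == 181  # 20..200 Hz inclusive at 1 Hz

    def test_zero_density_zero_power(self):
        psd = self._flat_psd()
        psd.density = np.zeros_like(psd.density)
        assert total_power(psd) == 0.0

    def test_total_power_matches_brute_force(self, rng):
        freqs = np.arange(0.0, 601.0)
        dens = rng.random(len(freqs))
        psd = PSDResult(freqs=freqs, density=dens, window_s=1.0, overlap=0.5)
        oracle = sum(d for f, d in zip(freqs, dens) if 20 <= f <= 200)
        assert total_power(psd) == pytest.approx(oracle, abs=1e-12)

    def test_flat_density_band_fractions(self):
        # half-open [20,80) and [80,140), closed-top [140,200]: 60/60/61 bins
        fracs = rpsd_bands(self._flat_psd())
        assert fracs == pytest.approx((60 / 181, 60 / 181, 61 / 181), abs=1e-12)

    def test_single_bin_concentration(self):
        psd = self._flat_psd()
        psd.density = np.zeros_like(psd.density)
        psd.density[100] = 5.0
        assert rpsd_bands(psd) == pytest.approx((0.0, 1.0, 0.0))

    def test_zero_total_power_yields_nan_with_warning(self):
        psd = self._flat_psd()
        psd.density = np.zeros_like(psd.density)
        with pytest.warns(UserWarning, match="rPSD undefined"):
            fracs = rpsd_bands(psd)
        assert all(np.isnan(fracs))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(0.0, 601.0)
        psd = PSDResult(
            freqs=freqs, density=rng.random(len(freqs)) + 1e-6, window_s=1.0, overlap=0.5
        )
        assert sum(rpsd_bands(psd)) == pytest.approx(1.0, abs=1e-9)


def _burst_epoch(amplitude, profile, seed=0, n_lower=3):
    """Noise-free epoch: zero baseline, band-shaped burst on lower channels."""
    from pelvimag.synthetic import _shaped_burst

    rng = np.random.default_rng(seed)
    n_sig = 12000
    burst = _shaped_burst(n_sig, FS, profile, amplitude, rng)
    data = np.zeros((n_lower, 15600))
    for i in range(n_lower):
        data[i, 3600:] = burst
    chans = [ChannelInfo(f"M{i}", ChannelRole.MMG_LOWER) for i in range(n_lower)]
    return Epoch(data=data, fs=FS, channels=chans, label="MK", onset_s=10.0)


class TestEpochFeatures:
    def test_band_profile_recovered(self):
        ep = _burst_epoch(60.0, (0.2, 0.6, 0.2), seed=4)
        rec = epoch_features(ep)
        assert (rec.rpsd_low, rec.rpsd_middle, rec.rpsd_high) == pytest.approx(
            (0.2, 0.6, 0.2), abs=0.05
        )

    def test_scale_equivariance(self):
        ep = _burst_epoch(40.0, (0.3, 0.4, 0.3), seed=9)
        scaled = Epoch(
            data=3.0 * ep.data,
            fs=ep.fs,
            channels=ep.channels,
            label=ep.label,
            onset_s=ep.onset_s,
        )
        a, b = epoch_features(ep), epoch_features(scaled)
        assert b.rms_fT == pytest.approx(3.0 * a.rms_fT, rel=1e-9)
        assert b.total_power == pytest.approx(9.0 * a.total_power, rel=1e-9)
        assert (b.rpsd_low, b.rpsd_middle, b.rpsd_high) == pytest.approx(
            (a.rpsd_low, a.rpsd_middle, a.rpsd_high), rel=1e-9
        )

    def test_zero_signal_degenerate(self):
        ep = _burst_epoch(60.0, (0.2, 0.6, 0.2))
        ep.data[:, 3600:] = 0.0
        with pytest.warns(UserWarning, match="rPSD undefined"):
            rec = epoch_features(ep)
        assert rec.rms_fT == pytest.approx(0.0)
        assert np.isnan(rec.rpsd_low)


class TestPowerMap:
    def test_burst_localizes_to_lower_sensors(self, quiet_spec):
        bursts = [BurstSpec(ExerciseLabel.MK, 60.0, (0.45, 0.35, 0.2))]
        rec, events = simulate_session(quiet_spec, bursts, seed=6)
        from pelvimag.epochs import extract_epochs

        eset = extract_epochs(rec, events, labels={"MK"})
        pmap = power_map(eset.epochs[0])
        assert pmap.roles[int(np.argmax(pmap.power))] is ChannelRole.MMG_LOWER

    def test_zero_data_zero_map(self):
        ep = _burst_epoch(60.0, (0.2, 0.6, 0.2))
        ep.data[:] = 0.0
        pmap = power_map(ep)
        np.testing.assert_array_equal(pmap.power, 0.0)

    def test_scale_squares_map(self):
        ep = _burst_epoch(60.0, (0.2, 0.6, 0.2), seed=2)
        p1 = power_map(ep)
        ep2 = Epoch(
            data=2.0 * ep.data,
            fs=ep.fs,
            channels=ep.channels,
            label=ep.label,
            onset_s=ep.onset_s,
        )
        p2 = power_map(ep2)
        np.testing.assert_allclose(p2.power, 4.0 * p1.power, rtol=1e-9)
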