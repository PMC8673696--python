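import numpy as np
import pytest

from conftest import two_channel_recording
from pelvimag.io_core import ChannelInfo, ChannelRole, Recording
from pelvimag.preprocess import (
    apply_subtr,
    bandpass_gain,
    bandpass_notch,
    fit_subtr,
    ica_denoise,
    remove_cardiac_emg,
)
from pelvimag.synthetic import cardiac_template_train

FS = 1200.0


def _coherent_power(x, ref):
    """Power of x linearly explained by ref (time-domain projection)."""
    return float(np.dot(x, ref) ** 2 / (np.dot(ref, ref) * len(x)))


class TestBandpassNotch:
    def test_passband_gain_matches_design(self):
        t = np.arange(int(20 * FS)) / FS
        rec = two_channel_recording(np.tile(np.sin(2 * np.pi * 100 * t), (2, 1)))
        out = bandpass_notch(rec)
        sl = slice(2400, -2400)  # avoid filter edge transients
        measured = np.sqrt(np.mean(out.data[0, sl] ** 2)) / np.sqrt(
            np.mean(rec.data[0, sl] ** 2)
        )
        assert measured == pytest.approx(bandpass_gain(100.0, FS), rel=0.02)
        assert measured == pytest.approx(1.0, rel=0.02)

    def test_line_tone_attenuated_30db(self):
        t = np.arange(int(20 * FS)) / FS
        rec = two_channel_recording(np.tile(np.sin(2 * np.pi * 60 * t), (2, 1)))
        out = bandpass_notch(rec)
        sl = slice(2400, -2400)
        ratio = np.sqrt(np.mean(out.data[0, sl] ** 2)) / np.sqrt(
            np.mean(rec.data[0, sl] ** 2)
        )
        assert ratio <= 10 ** (-30 / 20)

    def test_zero_input_zero_output(self):
        rec = two_channel_recording(np.zeros((2, 6000)))
        assert np.all(bandpass_notch(rec).data == 0.0)

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = two_channel_recording(np.zeros((2, 6000)))
        with pytest.raises(ValueError):
            bandpass_notch(rec, high=700.0)

    def test_zero_phase_no_delay(self):
        # impulse energy centroid stays put under forward-backward filtering
        data = np.zeros((2, 6000))
        data[:, 3000] = 1.0
        out = bandpass_notch(two_channel_recording(data))
        e = out.data[0] ** 2
        centroid = np.sum(np.arange(6000) * e) / np.sum(e)
        assert abs(centroid - 3000) <= 1.0

    def test_output_length_and_order_preserved(self, rng):
        rec = two_channel_recording(rng.standard_normal((2, 7000)))
        out = bandpass_notch(rec)
        assert out.data.shape == rec.data.shape
        assert [c.name for c in out.channels] == [c.name for c in rec.channels]


class TestSubtr:
    def test_constant_coupling_recovered(self, rng):
        n = int(30 * FS)
        ref = rng.standard_normal(n)
        rec = two_channel_recording(np.vstack([0.5 * ref, ref]))
        filt = fit_subtr(rec)
        occupied = (filt.freqs > 5) & (filt.freqs < 590)
        w = np.abs(filt.weights[occupied, 0, 0])
        assert np.median(w) == pytest.approx(0.5, rel=0.02)

    def test_uncorrelated_weights_shrink_with_length(self, rng):
        norms = []
        for dur in (20, 80):
            n = int(dur * FS)
            rec = two_channel_recording(
                np.vstack([rng.standard_normal(n), rng.standard_normal(n)])
            )
            filt = fit_subtr(rec)
            norms.append(np.median(np.abs(filt.weights[:, 0, 0])))
        # regression bias of uncorrelated series decays like 1/sqrt(frames)
        assert norms[1] < norms[0]
        assert norms[1] < 0.15

    def test_frequency_dependent_coupling_recovered(self, rng):
        n = int(60 * FS)
        ref = rng.standard_normal(n)
        spec = np.fft.rfft(ref)
        freqs = np.fft.rfftfreq(n, 1 / FS)
        lo = np.fft.irfft(np.where(freqs < 100, spec, 0), n)
        hi = np.fft.irfft(np.where(freqs >= 100, spec, 0), n)
        target = 0.8 * lo + 0.2 * hi
        rec = two_channel_recording(np.vstack([target, ref]))
        filt = fit_subtr(rec)
        w = np.abs(filt.weights[:, 0, 0])
        low_bins = (filt.freqs > 10) & (filt.freqs < 90)
        high_bins = (filt.freqs > 110) & (filt.freqs < 590)
        assert np.median(w[low_bins]) == pytest.approx(0.8, rel=0.10)
        assert np.median(w[high_bins]) == pytest.approx(0.2, rel=0.10)

    def test_mixture_cleaned_signal_preserved(self, rng):
        n = int(30 * FS)
        ref = rng.standard_normal(n)
        sig = rng.standard_normal(n)
        rec = two_channel_recording(np.vstack([sig + 0.5 * ref, ref]))
        out = apply_subtr(rec, fit_subtr(rec))
        before = _coherent_power(rec.data[0], ref)
        after = _coherent_power(out.data[0], ref)
        assert 10 * np.log10(before / after) >= 20.0
        sig_change_db = 10 * np.log10(np.mean(out.data[0] ** 2) / np.mean(sig**2))
        assert abs(sig_change_db) <= 1.0
        assert out.data.shape[1] == n
        np.testing.assert_array_equal(out.data[1], ref)  # reference untouched

    def test_zero_reference_identity(self, rng):
        n = int(30 * FS)
        sig = rng.standard_normal(n)
        rec = two_channel_recording(np.vstack([sig, np.zeros(n)]))
        out = apply_subtr(rec, fit_subtr(rec))
        np.testing.assert_allclose(out.data[0], sig, atol=1e-10)

    def test_second_pass_nearly_idempotent(self, rng):
        n = int(30 * FS)
        ref = rng.standard_normal(n)
        sig = rng.standard_normal(n)
        rec = two_channel_recording(np.vstack([sig + 0.5 * ref, ref]))
        once = apply_subtr(rec, fit_subtr(rec))
        twice = apply_subtr(once, fit_subtr(once))
        change_db = 10 * np.log10(np.mean(twice.data[0] ** 2) / np.mean(once.data[0] ** 2))
        assert abs(change_db) <= 1.0

    def test_matches_time_domain_least_squares(self, rng):
        # constant-coupling toy: STFT-domain solve vs direct LS subtraction
        # (per-bin estimation variance ~ 1/n_frames, so use a long record)
        n = int(80 * FS)
        ref = rng.standard_normal(n)
        sig = rng.standard_normal(n)
        rec = two_channel_recording(np.vstack([sig + 0.7 * ref, ref]))
        out = apply_subtr(rec, fit_subtr(rec))
        beta = np.dot(rec.data[0], ref) / np.dot(ref, ref)
        oracle = rec.data[0] - beta * ref
        resid_ratio = np.mean((out.data[0] - oracle) ** 2) / np.mean(oracle**2)
        assert resid_ratio <= 0.01

    def test_channel_mismatch_rejected(self, rng):
        rec = two_channel_recording(rng.standard_normal((2, int(30 * FS))))
        filt = fit_subtr(rec)
        other = Recording(
            rng.standard_normal((3, int(30 * FS))),
            fs=FS,
            channels=[
                ChannelInfo(f"M{i}", ChannelRole.MMG_LOWER) for i in range(3)
            ],
        )
        with pytest.raises(ValueError):
            apply_subtr(other, filt)

    def test_no_reference_channels_rejected(self, rng):
        rec = Recording(
            rng.standard_normal((2, int(30 * FS))),
            fs=FS,
            channels=[ChannelInfo(f"M{i}", ChannelRole.MMG_LOWER) for i in range(2)],
        )
        with pytest.raises(ValueError, match="reference"):
            fit_subtr(rec)


def _planted_cardiac_recording(rng, n_ch=6, dur_s=40.0):
    n = int(dur_s * FS)
    heart = cardiac_template_train(n, FS, rng)
    sources = [heart] + [rng.laplace(size=n) for _ in range(4)]
    mix = rng.normal(size=(n_ch, 5))
    mix[:, 0] = 5 * (0.5 + rng.random(n_ch))
    data = mix @ np.vstack(sources) + 0.01 * rng.standard_normal((n_ch, n))
    data = np.vstack([data, 10 * heart + 0.05 * rng.standard_normal(n)])
    chans = [ChannelInfo(f"M{i}", ChannelRole.MMG_LOWER) for i in range(n_ch)]
    chans.append(ChannelInfo("ECG1", ChannelRole.ECG))
    return Recording(data, fs=FS, channels=chans), heart, n_ch


class TestIcaDenoise:
    def test_planted_cardiac_removed(self, rng):
        rec, heart, n_ch = _planted_cardiac_recording(rng)
        out, report = ica_denoise(rec, seed=0)
        assert report.n_rejected >= 1
        assert any(r == "ecg-correlated" for _, r in report.rejected)

        def corr(d):
            return np.mean(
                [abs(np.corrcoef(d[i], heart)[0, 1]) for i in range(n_ch)]
            )

        assert corr(out.data) <= 0.2 * corr(rec.data)

    def test_nothing_rejected_is_round_trip(self, rng):
        rec, _, n_ch = _planted_cardiac_recording(rng)
        out, report = ica_denoise(
            rec, corr_threshold=1.01, edge_energy_threshold=1.01, seed=0
        )
        assert report.rejected == []
        scale = np.max(np.abs(rec.data[:n_ch]))
        err = np.max(np.abs(out.data[:n_ch] - rec.data[:n_ch])) / scale
        assert err <= 1e-6

    def test_deterministic_rejection(self, rng):
        rec, _, _ = _planted_cardiac_recording(rng)
        out1, r1 = ica_denoise(rec, seed=0)
        out2, r2 = ica_denoise(rec, seed=0)
        assert r1.rejected == r2.rejected
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_too_few_channels_rejected(self):
        rec = Recording(
            np.zeros((1, 1000)), fs=FS, channels=[ChannelInfo("M0", ChannelRole.MMG_LOWER)]
        )
        with pytest.raises(ValueError):
            ica_denoise(rec)


class TestRemoveCardiacEmg:
    def _emg_recording(self, rng, cardiac_gain):
        n = int(40 * FS)
        heart = cardiac_template_train(n, FS, rng)
        muscle = rng.standard_normal(n)
        emg = muscle + cardiac_gain * heart
        chans = [
            ChannelInfo("EMGP1", ChannelRole.EMG_PERINEUM),
            ChannelInfo("ECG1", ChannelRole.ECG),
        ]
        data = np.vstack([emg, heart + 0.01 * rng.standard_normal(n)])
        return Recording(data, fs=FS, channels=chans), heart, muscle

    def test_cardiac_coherent_power_reduced(self, rng):
        rec, heart, _ = self._emg_recording(rng, cardiac_gain=0.3)
        out = remove_cardiac_emg(rec)
        before = _coherent_power(rec.data[0], heart)
        after = _coherent_power(out.data[0], heart)
        assert 10 * np.log10(before / after) >= 20.0

    def test_null_mixture_power_preserved(self, rng):
        rec, _, muscle = self._emg_recording(rng, cardiac_gain=0.0)
        out = remove_cardiac_emg(rec)
        change = 10 * np.log10(np.mean(out.data[0] ** 2) / np.mean(rec.data[0] ** 2))
        assert abs(change) <= 1.0

    def test_missing_emg_rejected(self, rng):
        rec = Recording(
            rng.standard_normal((1, int(40 * FS))),
            fs=FS,
            channels=[ChannelInfo("ECG1", ChannelRole.ECG)],
        )
        with pytest.raises(ValueError, match="EMG"):
            remove_cardiac_emg(rec)
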