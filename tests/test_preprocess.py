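import numpy as np
import pytest

from nirsretest import (EvokedSpec, PreprocessParams, bandpass, block_average,
                        compute_snr, intensity_to_od, make_probe,
                        make_stim_schedule, od_to_hb, preprocess_recording,
                        prune_channels, simulate_session, spline_correct,
                        wavelet_correct)
from nirsretest.extinction import extinction_matrix
from nirsretest.preprocess import EmptyRecordingError, ODRecording
from nirsretest.synth import DPF, RawRecording

from conftest import NO_NOISE, QUIET_PHYSIO


def _raw_from_intensity(inten, probe, schedule, fs=8.9):
    return RawRecording(intensity=inten, fs=fs, probe=probe,
                        schedule=schedule)


@pytest.fixture(scope="module")
def tiny():
    probe = make_probe("single")
    sched = make_stim_schedule(1, 2, 10, 10, seed=0)
    return probe, sched


class TestSNR:
    def test_constant_signal_infinite(self, tiny):
        probe, sched = tiny
        raw = _raw_from_intensity(np.full((1, 2, 100), 100.0), probe, sched)
        assert np.all(np.isinf(compute_snr(raw)))

    def test_mean_over_sd(self, tiny):
        probe, sched = tiny
        x = np.full(1000, 80.0)
        x[::2] += 10.0
        x[1::2] -= 10.0
        raw = _raw_from_intensity(np.tile(x, (1, 2, 1)), probe, sched)
        assert compute_snr(raw)[0, 0] == pytest.approx(8.0)

    def test_alternating_series_population_sd(self, tiny):
        probe, sched = tiny
        x = np.tile([90.0, 110.0], 500)
        raw = _raw_from_intensity(np.tile(x, (1, 2, 1)), probe, sched)
        assert compute_snr(raw)[0, 0] == pytest.approx(10.0)


class TestPruning:
    def _two_channel_raw(self, snr_a, snr_b):
        """Two channels; alternating series with chosen mean/SD ratios."""
        probe = make_probe("compact")
        sched = make_stim_schedule(1, 2, 10, 10, seed=0)
        n_ch = probe.n_channels
        inten = np.full((n_ch, 2, 1000), 100.0)
        alt = np.tile([1.0, -1.0], 500)
        for (ch, wl), snr in {**snr_a, **snr_b}.items():
            inten[ch, wl] = 100.0 + alt * (100.0 / snr)
        return RawRecording(intensity=inten, fs=8.9, probe=probe,
                            schedule=sched)

    def test_either_wavelength_rule(self):
        raw = self._two_channel_raw({(0, 0): 7.9}, {(0, 1): 20.0})
        keep, pruned = prune_channels(raw)
        assert 0 in pruned and 0 not in keep

    def test_boundary_snr_kept(self):
        raw = self._two_channel_raw({(1, 0): 8.0}, {(1, 1): 8.0})
        keep, pruned = prune_channels(raw)
        assert 1 in keep and not pruned

    def test_all_good_identity(self, realistic_session):
        keep, pruned = prune_channels(realistic_session)
        assert len(keep) + len(pruned) == realistic_session.n_channels

    def test_all_pruned_raises(self, tiny):
        probe, sched = tiny
        rng = np.random.default_rng(0)
        inten = np.abs(rng.normal(1, 5, size=(1, 2, 500))) + 0.01
        raw = _raw_from_intensity(inten, probe, sched)
        with pytest.raises(EmptyRecordingError):
            intensity_to_od(raw)


class TestOpticalDensity:
    def test_constant_intensity_zero_od(self, tiny):
        probe, sched = tiny
        raw = _raw_from_intensity(np.full((1, 2, 50), 123.0), probe, sched)
        od = intensity_to_od(raw, prune=False)
        assert np.allclose(od.od, 0.0)

    def test_decade_drop_gives_unit_od(self, tiny):
        probe, sched = tiny
        n = 1000
        inten = np.full((1, 2, n), 100.0)
        inten[0, :, 10] = 10.0
        raw = _raw_from_intensity(inten, probe, sched)
        od = intensity_to_od(raw, prune=False)
        i0 = inten[0, 0].mean()
        assert od.od[0, 0, 10] == pytest.approx(-np.log10(10.0 / i0))
        assert od.od[0, 0, 10] - od.od[0, 0, 0] == pytest.approx(1.0)

    def test_nonpositive_intensity_raises(self, tiny):
        probe, sched = tiny
        inten = np.full((1, 2, 50), 100.0)
        inten[0, 1, 7] = 0.0
        raw = _raw_from_intensity(inten, probe, sched)
        with pytest.raises(ValueError, match="sample 7"):
            intensity_to_od(raw, prune=False)


def _od_recording(x, fs=8.9):
    """Wrap a 1-D series as a single-channel ODRecording (both wavelengths)."""
    probe = make_probe("single")
    sched = make_stim_schedule(1, 2, 10, 10, seed=0)
    od = np.tile(x, (1, 2, 1)).astype(float)
    return ODRecording(od=od, fs=fs, probe=probe, schedule=sched,
                       channel_idx=np.array([0]))


class TestSplineCorrection:
    def test_clean_signal_unchanged(self):
        t = np.arange(3000) / 8.9
        x = 0.01 * np.sin(2 * np.pi * 0.05 * t)
        od = _od_recording(x)
        out = spline_correct(od)
        assert np.allclose(out.od, od.od)

    def test_step_artifact_reduced(self):
        rng = np.random.default_rng(0)
        n = 3000
        x = 0.001 * rng.standard_normal(n)
        sd = x.std()
        x[1500:] += 10 * sd * 13.5 / 10  # a large persistent shift
        od = _od_recording(x)
        out = spline_correct(od)
        step_before = abs(np.mean(x[1520:1700]) - np.mean(x[1300:1480]))
        y = out.od[0, 0]
        step_after = abs(np.mean(y[1520:1700]) - np.mean(y[1300:1480]))
        assert step_after <= 0.2 * step_before

    def test_spike_reduced_below_detection(self):
        rng = np.random.default_rng(1)
        n = 3000
        x = 0.001 * rng.standard_normal(n)
        x[1000:1004] += 0.3
        od = _od_recording(x)
        out = spline_correct(od)
        from nirsretest.preprocess import _motion_flags, PreprocessParams
        p = PreprocessParams()
        assert _motion_flags(x, 8.9, p.motion_window, p.motion_sd_mult,
                             p.motion_amp_thresh).any()
        y = out.od[0, 0]
        assert np.abs(y[990:1014]).max() < np.abs(x[990:1014]).max() * 0.3

    def test_window_longer_than_recording(self):
        od = _od_recording(np.zeros(5))
        with pytest.raises(ValueError):
            spline_correct(od, PreprocessParams(motion_window=10.0))


class TestWaveletCorrection:
    def test_noop_limit_large_alpha(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4096) * 0.001
        od = _od_recording(x)
        out = wavelet_correct(od, PreprocessParams(wavelet_alpha=1e9))
        assert np.allclose(out.od, od.od, atol=1e-10)

    def test_spike_energy_removed(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096) * 0.001
        x[2000] += 0.5
        od = _od_recording(x)
        out = wavelet_correct(od)
        spike_before = x[1995:2005]
        spike_after = out.od[0, 0, 1995:2005]
        assert np.sum(spike_after ** 2) <= 0.1 * np.sum(spike_before ** 2)

    def test_slow_sinusoid_preserved(self):
        t = np.arange(8192) / 8.9
        x = 0.01 * np.sin(2 * np.pi * 0.02 * t)
        x[4000] += 0.5
        od = _od_recording(x)
        out = wavelet_correct(od)
        y = out.od[0, 0]
        ref = np.sin(2 * np.pi * 0.02 * t)
        amp = 2 * np.mean(y * ref)  # LS amplitude on the known carrier
        assert amp == pytest.approx(0.01, rel=0.05)

    def test_too_short_recording(self):
        od = _od_recording(np.zeros(2))
        with pytest.raises(ValueError):
            wavelet_correct(od)

    def test_idempotent_on_clean_data(self):
        t = np.arange(4096) / 8.9
        x = 0.01 * np.sin(2 * np.pi * 0.05 * t)
        od = _od_recording(x)
        once = wavelet_correct(od)
        twice = wavelet_correct(once)
        rms = np.sqrt(np.mean(once.od ** 2))
        drms = np.sqrt(np.mean((twice.od - once.od) ** 2))
        assert drms < 0.01 * rms


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        od = _od_recording(np.zeros(100))
        hb = od_to_hb(od)
        assert np.allclose(hb.hbo, 0) and np.allclose(hb.hbr, 0)

    def test_known_concentration_recovered(self):
        ext = extinction_matrix()
        d = 3.0
        true = np.array([1.0, -0.5])  # uM
        od_vals = ext @ true * d * DPF
        probe = make_probe("single")
        sched = make_stim_schedule(1, 2, 10, 10, seed=0)
        od = ODRecording(
            od=np.repeat(od_vals.reshape(1, 2, 1), 100, axis=2),
            fs=8.9, probe=probe, schedule=sched, channel_idx=np.array([0]))
        hb = od_to_hb(od)
        assert hb.hbo[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert hb.hbr[0, 0] == pytest.approx(-0.5, abs=1e-12)

    def test_doubling_distance_halves_concentration(self):
        x = np.full(50, 0.01)
        od = _od_recording(x)
        hb1 = od_to_hb(od)
        hb2 = od_to_hb(od, dpf=2 * DPF)
        assert np.allclose(hb2.hbo, hb1.hbo / 2)

    def test_singular_extinction_raises(self):
        od = _od_recording(np.zeros(10))
        with pytest.raises(ValueError):
            od_to_hb(od, extinction=np.ones((2, 2)))


class TestBandpass:
    def _hb(self, x, fs=8.9):
        od = _od_recording(np.zeros(len(x)), fs=fs)
        hb = od_to_hb(od)
        hb.hbo[0] = x
        hb.hbr[0] = x
        return hb

    def test_frequency_response(self):
        """Zero-phase response: >=20 dB down at cardiac 1.1 Hz and DC,
        within 1 dB of unity at mid-band 0.05 Hz."""
        from scipy.signal import butter, sosfreqz
        fs = 8.9
        sos = butter(3, [0.005, 0.5], btype="bandpass", fs=fs, output="sos")
        freqs = np.array([1e-4, 0.05, 1.1])
        _, h = sosfreqz(sos, worN=2 * np.pi * freqs / fs)
        gain2 = np.abs(h) ** 2  # forward-backward application
        assert gain2[2] <= 10 ** (-20 / 10)
        assert gain2[0] <= 10 ** (-20 / 10)
        assert abs(10 * np.log10(gain2[1])) < 1.0

    def test_midband_preserved(self):
        fs = 8.9
        t = np.arange(int(fs * 600)) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(self._hb(x))
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(out.hbo[0, mid]).max() == pytest.approx(1.0, rel=0.1)

    def test_zero_in_zero_out(self):
        out = bandpass(self._hb(np.zeros(2000)))
        assert np.allclose(out.hbo, 0)

    def test_bad_band_edges(self):
        hb = self._hb(np.zeros(2000))
        with pytest.raises(ValueError):
            bandpass(hb, low=0.005, high=5.0)


class TestFullChain:
    def test_noiseless_recovery_within_filter_ripple(self, isolated_session):
        """Simulate -> full preprocess -> block-average peak ~ truth."""
        hb = preprocess_recording(isolated_session, motion_correction=False)
        avg = block_average(hb)
        gt = isolated_session.ground_truth
        kept = hb.channel_idx
        ch = int(np.argmax(gt.amp_hbo[kept]))
        peak = avg["hbo_mean"][ch].max()
        assert peak == pytest.approx(gt.amp_hbo[kept[ch]], rel=0.05)

    def test_stage_order_logged(self, realistic_session):
        hb = preprocess_recording(realistic_session)
        stages = [s[0] for s in hb.log]
        assert stages == ["prune", "od", "spline", "wavelet", "mbll",
                          "bandpass"]

    def test_band_limited_output(self, realistic_session):
        hb = preprocess_recording(realistic_session)
        from scipy.signal import periodogram
        f, p = periodogram(hb.hbo[0], fs=hb.fs)
        assert p[f > 0.6].sum() < 0.01 * p.sum()
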