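"""Multitaper estimator tests: tapers, spectrogram calibration, contrasts."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal

import ieegspectra as ie
from ieegspectra.spectral import band_bins


class TestDPSS:
    def test_orthonormality_and_concentrations(self):
        ts = ie.compute_dpss(1000, 3.0, 5)
        gram = ts.tapers @ ts.tapers.T
        assert np.abs(gram - np.eye(5)).max() < 1e-8
        assert np.all(np.diff(ts.concentrations) < 0)
        assert np.all((ts.concentrations > 0) & (ts.concentrations < 1))
        assert ts.concentrations[0] > 0.99

    def test_matches_scipy_reference(self):
        """Independent cross-check against scipy's DPSS construction."""
        ts = ie.compute_dpss(512, 2.5, 4)
        ref, ref_conc = scipy.signal.windows.dpss(512, 2.5, 4, return_ratios=True)
        np.testing.assert_allclose(np.abs(ts.tapers), np.abs(ref), atol=1e-10)
        np.testing.assert_allclose(ts.concentrations, ref_conc, atol=1e-9)

    def test_sign_change_counts(self):
        """Taper k crosses zero exactly k-1 times."""
        ts = ie.compute_dpss(1000, 3.0, 5)
        for k in range(5):
            crossings = int(np.sum(np.diff(np.sign(ts.tapers[k])) != 0))
            assert crossings == k

    def test_leading_taper_symmetric(self):
        ts = ie.compute_dpss(501, 2.0, 1)
        np.testing.assert_allclose(ts.tapers[0], ts.tapers[0][::-1], atol=1e-10)

    def test_super_resolution_rejected(self):
        with pytest.raises(ValueError):
            ie.compute_dpss(1000, 2.0, 5)  # K > 2*NW
        with pytest.raises(ValueError):
            ie.compute_dpss(4, 3.0, 5)  # N <= K


class TestSpectrogram:
    def test_parseval_white_noise(self, rng):
        rec = ie.Recording(rng.standard_normal((1, 500 * 120)), 500.0, ["a"])
        est = ie.multitaper_spectrogram(rec)
        total = np.trapezoid(est.power[0].mean(axis=0), est.freqs)
        assert total == pytest.approx(1.0, rel=0.05)

    def test_sinusoid_mass_confined_to_half_bandwidth(self):
        t = np.arange(500 * 60) / 500.0
        rec = ie.Recording(np.sin(2 * np.pi * 10 * t)[None, :], 500.0, ["a"])
        est = ie.multitaper_spectrogram(rec)
        m = est.power[0].mean(axis=0)
        inband = (est.freqs >= 10 - 1.5) & (est.freqs <= 10 + 1.5)
        assert m[inband].sum() / m.sum() > 0.99
        assert est.freqs[np.argmax(m)] == pytest.approx(10.0, abs=0.5)

    @pytest.mark.parametrize(
        "dur,expected", [(600.0, 399), (2.0, 1), (3.4, 1), (3.5, 2)]
    )
    def test_window_count(self, rng, dur, expected):
        rec = ie.Recording(rng.standard_normal((1, int(500 * dur))), 500.0, ["a"])
        est = ie.multitaper_spectrogram(rec)
        assert est.times.size == expected

    def test_boxcar_single_taper_equals_periodogram(self, rng):
        """With a boxcar taper substituted, the machinery reduces to a plain
        windowed periodogram."""
        fs = 500.0
        x = rng.standard_normal(int(fs * 20))
        rec = ie.Recording(x[None, :], fs, ["a"])
        n = int(fs * 2)
        boxcar = np.full((1, n), 1.0 / np.sqrt(n))
        est = ie.multitaper_spectrogram(rec, tapers=boxcar, window_detrend="none")
        seg = x[:n]
        ref = np.abs(np.fft.rfft(boxcar[0] * seg)) ** 2 * (2.0 / fs)
        ref[0] /= 2.0
        ref[-1] /= 2.0
        np.testing.assert_allclose(est.power[0, 0], ref, rtol=1e-10, atol=1e-14)

    def test_variance_reduction_k5_vs_k1(self, rng):
        """Averaging 5 tapers cuts per-bin variance to about 1/5."""
        dur = 200 * 1.5 + 2
        rec = ie.Recording(rng.standard_normal((1, int(500 * dur))), 500.0, ["a"])
        v5 = ie.multitaper_spectrogram(rec, K=5).power[0].var(axis=0)
        v1 = ie.multitaper_spectrogram(rec, K=1, NW=1.0).power[0].var(axis=0)
        ratio = (v5[5:-5] / v1[5:-5]).mean()
        assert 0.15 <= ratio <= 0.3

    def test_shift_by_integer_steps_preserves_window_psds(self, rng):
        fs, step = 500.0, 1.5
        x = rng.standard_normal(int(fs * 30))
        est_full = ie.multitaper_spectrogram(ie.Recording(x[None, :], fs, ["a"]))
        shifted = x[int(step * fs):]
        est_shift = ie.multitaper_spectrogram(ie.Recording(shifted[None, :], fs, ["a"]))
        n = est_shift.times.size
        np.testing.assert_allclose(est_shift.power[0], est_full.power[0, 1 : n + 1])
        np.testing.assert_allclose(est_shift.times + step, est_full.times[1 : n + 1])

    def test_fractional_overlap_reading(self, rng):
        rec = ie.Recording(rng.standard_normal((1, 500 * 20)), 500.0, ["a"])
        est = ie.multitaper_spectrogram(rec, overlap=0.5, overlap_is_fraction=True)
        assert est.params["step"] == pytest.approx(1.0)

    def test_invalid_inputs(self, rng):
        short = ie.Recording(rng.standard_normal((1, 100)), 500.0, ["a"])
        with pytest.raises(ValueError):
            ie.multitaper_spectrogram(short)  # shorter than T
        odd = ie.Recording(rng.standard_normal((1, 5000)), 333.3, ["a"])
        with pytest.raises(ValueError):
            ie.multitaper_spectrogram(odd)  # fs*T not integral


class TestDecibels:
    @pytest.mark.parametrize("power,db", [(1.0, 0.0), (100.0, 20.0), (1e-3, -30.0)])
    def test_scale(self, power, db):
        assert ie.to_decibels(power) == pytest.approx(db)

    def test_zero_floored_negative_rejected(self):
        out = ie.to_decibels(np.array([0.0, 1.0]))
        assert out[0] == -300.0 and out[1] == 0.0
        with pytest.raises(ValueError):
            ie.to_decibels(np.array([-1.0]))


def _epochs(*rows):
    return pd.DataFrame(rows, columns=["condition", "start_s", "end_s"])


class TestConditionPSD:
    def test_stationary_conditions_agree(self, rng):
        rec = ie.Recording(rng.standard_normal((1, 500 * 120)), 500.0, ["a"])
        est = ie.multitaper_spectrogram(rec)
        psd = ie.condition_mean_psd(
            est, _epochs(("baseline", 0.0, 60.0), ("ketamine", 60.0, 120.0))
        )
        diff = psd.psd_db[0, 1] - psd.psd_db[0, 0]
        assert np.abs(diff[2:]).max() < 2.0  # sampling error only

    def test_straddling_windows_excluded(self, rng):
        """Windows crossing a condition boundary count for neither side."""
        fs = 500.0
        rec = ie.Recording(rng.standard_normal((1, int(fs * 12))), fs, ["a"])
        est = ie.multitaper_spectrogram(rec)
        epochs = _epochs(("a", 0.0, 6.25), ("b", 6.25, 12.0))
        T = est.params["T"]
        w0, w1 = est.times - T / 2, est.times + T / 2
        in_a = (w0 >= 0) & (w1 <= 6.25)
        in_b = (w0 >= 6.25) & (w1 <= 12.0)
        straddle = ~(in_a | in_b)
        assert straddle.any()  # the boundary does split at least one window
        psd = ie.condition_mean_psd(est, epochs)
        expect_a = ie.to_decibels(est.power[0, in_a].mean(axis=0))
        np.testing.assert_allclose(psd.psd_db[0, 0], expect_a)

    def test_empty_condition_errors_with_name(self, rng):
        rec = ie.Recording(rng.standard_normal((1, 500 * 10)), 500.0, ["a"])
        est = ie.multitaper_spectrogram(rec)
        with pytest.raises(ValueError, match="gap"):
            ie.condition_mean_psd(est, _epochs(("a", 0.0, 8.0), ("gap", 8.0, 9.0)))


class TestBandContrast:
    def _psd(self, freqs, db_a, db_b):
        return ie.ConditionPSD(
            freqs=freqs,
            conditions=["a", "b"],
            psd_db=np.stack([db_a, db_b])[None, :, :],
            channel_ids=["c1"],
        )

    def test_identical_psds_zero(self):
        freqs = np.arange(0, 100.5, 0.5)
        db = np.linspace(-10, -40, freqs.size)
        psd = self._psd(freqs, db, db)
        for mode in ("mean", "sum"):
            out = ie.band_power_change(psd, ie.BandDef("alpha", 8, 15), "b", "a", mode=mode)
            assert out["value_db"].iloc[0] == pytest.approx(0.0)

    def test_tenfold_ratio_modes(self):
        freqs = np.arange(0, 100.5, 0.5)
        db_a = np.zeros(freqs.size)
        psd = self._psd(freqs, db_a, db_a + 10.0)
        band = ie.BandDef("alpha", 8, 15)
        n_bins = int(band_bins(freqs, band).sum())
        mean_out = ie.band_power_change(psd, band, "b", "a", mode="mean")
        sum_out = ie.band_power_change(psd, band, "b", "a", mode="sum")
        assert mean_out["value_db"].iloc[0] == pytest.approx(10.0)
        assert sum_out["value_db"].iloc[0] == pytest.approx(10.0 * n_bins)

    def test_half_open_bands_share_no_bins(self):
        freqs = np.arange(0, 100.5, 0.5)
        beta = band_bins(freqs, ie.BandDef("beta", 15, 25))
        gamma = band_bins(freqs, ie.BandDef("gamma", 25, 55))
        assert not np.any(beta & gamma)
        assert freqs[beta][-1] == 24.5 and freqs[gamma][0] == 25.0

    def test_empty_band_rejected(self):
        freqs = np.arange(0, 100.5, 0.5)
        psd = self._psd(freqs, np.zeros(freqs.size), np.zeros(freqs.size))
        with pytest.raises(ValueError):
            ie.band_power_change(psd, ie.BandDef("none", 30.1, 30.2), "b", "a")

    def test_injected_alpha_decrease_recovered(self):
        """A generator-injected -15 dB occipital alpha effect comes back
        within 1 dB through spectrogram + condition PSD + band contrast."""
        cfg = ie.SynthConfig(
            fs_raw=512.0,
            epoch_durations={"baseline": 300.0, "ketamine": 300.0},
            shanks=[ie.ShankSpec("oc", 3, "lateraloccipital")],
            effects=[ie.EffectSpec("ketamine", "occipital", (8.0, 15.0), -15.0)],
            line_noise=(60.0, 1, (1.0,)),
            n_subjects=1,
            seed=21,
        )
        rec, ch, ep = ie.generate_study(cfg)
        brec, _ = ie.bipolar_montage(ie.detrend_full(rec), ch)
        est = ie.multitaper_spectrogram(ie.resample_to(brec, 256.0))
        psd = ie.condition_mean_psd(est, ep)
        out = ie.band_power_change(psd, ie.BandDef("alpha", 8, 15), "ketamine", "baseline")
        assert out["value_db"].mean() == pytest.approx(-15.0, abs=1.0)
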