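"""Conditioning-chain tests: notch, resampling, detrend, exclusion, montage."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal

import ieegspectra as ie


def _peak_power(x, fs, f0, halfwidth=0.5, nperseg=16384):
    f, p = scipy.signal.welch(x, fs=fs, nperseg=min(nperseg, x.size))
    return p[np.abs(f - f0) <= halfwidth].sum()


class TestNotch:
    fs = 2000.0

    def _rec(self, x):
        return ie.Recording(x[None, :], self.fs, ["a"])

    @pytest.mark.parametrize("f0", [60.0, 120.0])
    def test_harmonic_attenuated_30db(self, f0, rng):
        t = np.arange(int(self.fs * 30)) / self.fs
        x = 5.0 * np.sin(2 * np.pi * f0 * t) + 0.1 * rng.standard_normal(t.size)
        out = ie.notch_filter(self._rec(x))
        atten = 10 * np.log10(_peak_power(x, self.fs, f0) / _peak_power(out.data[0], self.fs, f0))
        assert atten >= 30.0

    def test_passband_neutral_on_white_noise(self, rng):
        x = rng.standard_normal(int(self.fs * 30))
        out = ie.notch_filter(self._rec(x))
        f, p0 = scipy.signal.welch(x, fs=self.fs, nperseg=4096)
        _, p1 = scipy.signal.welch(out.data[0], fs=self.fs, nperseg=4096)
        keep = f > 1.0
        for h in range(1, 17):
            keep &= np.abs(f - 60.0 * h) > 3.0
        assert abs(p1[keep].sum() / p0[keep].sum() - 1.0) < 0.01
        assert np.abs(10 * np.log10(p1[keep] / p0[keep])).max() < 1.0

    def test_base_above_nyquist_rejected(self, rng):
        rec = ie.Recording(rng.standard_normal((1, 1000)), 100.0, ["a"])
        with pytest.raises(ValueError):
            ie.notch_filter(rec, base=60.0)


class TestResample:
    def test_sinusoid_amplitude_preserved(self):
        fs = 2000.0
        t = np.arange(int(fs * 20)) / fs
        rec = ie.Recording(np.sin(2 * np.pi * 10 * t)[None, :], fs, ["a"])
        out = ie.resample_to(rec, 500.0)
        assert out.fs == 500.0
        interior = out.data[0][500:-500]
        assert np.sqrt(2) * interior.std() == pytest.approx(1.0, rel=0.01)

    def test_length_contract(self, rng):
        n_in = 40001
        rec = ie.Recording(rng.standard_normal((1, n_in)), 2000.0, ["a"])
        out = ie.resample_to(rec, 500.0)
        assert abs(out.n_samples - round(n_in * 500 / 2000)) <= 1

    def test_alias_stopband(self, rng):
        """A strong 700 Hz tone must not alias into the 500 Hz output band."""
        fs = 2000.0
        t = np.arange(int(fs * 20)) / fs
        x = np.sin(2 * np.pi * 700 * t) + 0.01 * rng.standard_normal(t.size)
        out = ie.resample_to(ie.Recording(x[None, :], fs, ["a"]), 500.0)
        # 700 Hz would fold to 200 Hz after naive decimation
        alias = _peak_power(out.data[0], 500.0, 200.0, nperseg=4096)
        floor = _peak_power(out.data[0], 500.0, 100.0, nperseg=4096)
        assert alias < 10.0 * floor

    def test_identity_and_upsample_rejected(self, small_recording):
        same = ie.resample_to(small_recording, small_recording.fs)
        np.testing.assert_array_equal(same.data, small_recording.data)
        with pytest.raises(ValueError):
            ie.resample_to(small_recording, 2 * small_recording.fs)


class TestDetrend:
    def test_pure_trend_removed(self):
        t = np.arange(5000) / 500.0
        rec = ie.Recording((3.0 + 0.7 * t)[None, :], 500.0, ["a"])
        out = ie.detrend_full(rec)
        assert np.abs(out.data).max() < 1e-9 * np.abs(rec.data).max()

    def test_sinusoid_recovered_under_trend(self):
        t = np.arange(50000) / 500.0
        s = np.sin(2 * np.pi * 7.0 * t)
        rec = ie.Recording((s - 5.0 + 0.3 * t)[None, :], 500.0, ["a"])
        out = ie.detrend_full(rec)
        r = np.corrcoef(out.data[0], s)[0, 1]
        assert r > 0.999

    def test_idempotent(self, small_recording):
        once = ie.detrend_full(small_recording)
        twice = ie.detrend_full(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)


class TestExclusionAndMontage:
    def test_no_flags_identity(self, small_recording, small_channels):
        rec, ch = ie.drop_excluded(small_recording, small_channels)
        assert rec.channel_ids == small_recording.channel_ids
        assert len(ch) == len(small_channels)

    def test_flagged_removed_order_preserved(self, small_recording, small_channels):
        channels = small_channels.copy()
        channels.loc[[1, 4, 6], "excluded"] = True
        rec, ch = ie.drop_excluded(small_recording, channels)
        expected = channels.loc[~channels["excluded"], "contact_id"].tolist()
        assert rec.channel_ids == expected == ch["contact_id"].tolist()

    def test_unknown_contact_named_in_error(self, small_recording, small_channels):
        channels = small_channels.copy()
        channels.loc[0, "contact_id"] = "sub01:zz:9"
        with pytest.raises(KeyError, match="zz:9"):
            ie.drop_excluded(small_recording, channels)

    def test_full_montage_pair_count(self):
        """10 shanks x 10 contacts, none excluded -> 90 bipolar channels."""
        cfg = ie.SynthConfig(
            epoch_durations={"baseline": 4.0}, fs_raw=512.0,
            line_noise=(60.0, 1, (1.0,)), effects=[], n_subjects=1,
        )
        rec, ch, _ = ie.generate_study(cfg)
        brec, bch = ie.bipolar_montage(rec, ch)
        assert len(bch) == 90 == brec.n_channels
        assert len(bch) == ie.expected_bipolar_count(ch)

    def test_derived_trace_and_label(self, small_recording, small_channels):
        brec, bch = ie.bipolar_montage(small_recording, small_channels)
        # deeper minus shallower, label from deeper contact
        np.testing.assert_array_equal(
            brec.data[0], small_recording.data[0] - small_recording.data[1]
        )
        assert bch["fine_label"].iloc[0] == "superiorfrontal"
        assert bch["contact_id"].iloc[0] == "sub01:sA:1-2"

    def test_common_mode_rejection(self, small_recording, small_channels, rng):
        shared = rng.standard_normal(small_recording.n_samples)
        shifted = ie.Recording(
            small_recording.data + shared[None, :],
            small_recording.fs,
            small_recording.channel_ids,
        )
        b0, _ = ie.bipolar_montage(small_recording, small_channels)
        b1, _ = ie.bipolar_montage(shifted, small_channels)
        np.testing.assert_allclose(b0.data, b1.data, atol=1e-10)

    def test_gap_breaks_chain(self):
        """One mid-shank exclusion on a 10-contact shank leaves 7 pairs."""
        rows = [
            {
                "subject": "s", "contact_id": f"s:x:{p}", "shank_id": "x",
                "position": p, "fine_label": "insula", "excluded": p == 4,
            }
            for p in range(1, 11)
        ]
        channels = pd.DataFrame(rows)
        rec = ie.Recording(np.zeros((10, 1000)), 500.0, channels["contact_id"].tolist())
        rec2, ch2 = ie.drop_excluded(rec, channels)
        _, bch = ie.bipolar_montage(rec2, ch2)
        assert len(bch) == 7
        assert ie.expected_bipolar_count(channels) == 7

    def test_single_survivor_shank_yields_no_pairs(self):
        rows = [
            {
                "subject": "s", "contact_id": f"s:x:{p}", "shank_id": "x",
                "position": p, "fine_label": "insula", "excluded": p > 1,
            }
            for p in range(1, 4)
        ]
        channels = pd.DataFrame(rows)
        rec = ie.Recording(np.zeros((3, 100)), 100.0, channels["contact_id"].tolist())
        rec2, ch2 = ie.drop_excluded(rec, channels)
        brec, bch = ie.bipolar_montage(rec2, ch2)
        assert len(bch) == 0 and brec.n_channels == 0

    @pytest.mark.parametrize("n_excl", [0, 3, 7])
    def test_pair_count_matches_enumeration_oracle(self, n_excl, rng):
        """Montage bookkeeping equals exhaustive adjacent-pair enumeration."""
        rows = []
        for shank in "abc":
            for p in range(1, 8):
                rows.append(
                    {
                        "subject": "s", "contact_id": f"s:{shank}:{p}", "shank_id": shank,
                        "position": p, "fine_label": "insula", "excluded": False,
                    }
                )
        channels = pd.DataFrame(rows)
        flags = rng.choice(len(channels), size=n_excl, replace=False)
        channels.loc[flags, "excluded"] = True
        rec = ie.Recording(
            rng.standard_normal((len(channels), 500)), 500.0,
            channels["contact_id"].tolist(),
        )
        rec2, ch2 = ie.drop_excluded(rec, channels)
        _, bch = ie.bipolar_montage(rec2, ch2)
        assert len(bch) == ie.expected_bipolar_count(channels)


class TestChainIdempotence:
    def test_conditioning_twice_equals_once_in_passband(self, rng):
        """Re-running the conditioned signal through notch -> resample ->
        detrend changes no passband PSD bin by more than 1 dB.  Bins within
        +/-3 Hz of a notch harmonic are excluded: they sit in the filter's
        transition region, where a second pass necessarily deepens
        near-floor attenuation.  (The montage stage is a re-referencing,
        not a filter, and is by construction not re-applicable.)"""
        fs = 2000.0
        data = rng.standard_normal((2, int(fs * 40)))
        rec = ie.Recording(data, fs, ["a", "b"])

        def condition(r):
            return ie.detrend_full(ie.resample_to(ie.notch_filter(r), 500.0))

        once = condition(rec)
        twice = condition(once)
        f, p1 = scipy.signal.welch(once.data, fs=once.fs, nperseg=2048, axis=-1)
        _, p2 = scipy.signal.welch(twice.data, fs=twice.fs, nperseg=2048, axis=-1)
        keep = (f >= 0.5) & (f <= 200.0)
        for h in range(1, 5):
            keep &= np.abs(f - 60.0 * h) > 3.0
        db = np.abs(10 * np.log10(p2[:, keep] / p1[:, keep]))
        assert db.max() < 1.0
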