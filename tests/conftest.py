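"""Shared fixtures and independent oracles for the test suite.

The Welch-periodogram band-power oracle is deliberately independent of the
package's multitaper path: scipy.signal.welch with Hann windows, band
integrals taken with edges inset by twice the oracle's own resolution
bandwidth so that window leakage at band edges does not contaminate the
measurement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.signal

import ieegspectra as ie


def welch_band_power(x: np.ndarray, fs: float, lo: float, hi: float,
                     nperseg: int = 8192) -> float:
    """Band-integrated Welch PSD with leakage-guarded edges."""
    nperseg = min(nperseg, x.size)
    f, p = scipy.signal.welch(x, fs=fs, nperseg=nperseg)
    guard = 2.0 * fs / nperseg
    m = (f >= lo + guard) & (f < hi - guard)
    assert m.any(), "band too narrow for the oracle resolution"
    return float(p[m].sum())


def welch_contrast_db(x: np.ndarray, fs: float, lo: float, hi: float,
                      int_a: tuple[float, float], int_b: tuple[float, float]) -> float:
    """dB band-power contrast between two intervals of one trace."""
    a = x[int(int_a[0] * fs): int(int_a[1] * fs)]
    b = x[int(int_b[0] * fs): int(int_b[1] * fs)]
    return 10.0 * np.log10(
        welch_band_power(b, fs, lo, hi) / welch_band_power(a, fs, lo, hi)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_channels() -> pd.DataFrame:
    """Two shanks x 4 contacts, one subject, nothing excluded."""
    rows = []
    for shank in ("sA", "sB"):
        for pos in range(1, 5):
            rows.append(
                {
                    "subject": "sub01",
                    "contact_id": f"sub01:{shank}:{pos}",
                    "shank_id": shank,
                    "position": pos,
                    "fine_label": "superiorfrontal" if shank == "sA" else "lateraloccipital",
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_recording(rng, small_channels) -> ie.Recording:
    n = int(500 * 30)
    data = rng.standard_normal((len(small_channels), n))
    return ie.Recording(data, 500.0, small_channels["contact_id"].tolist())


def tiny_study_config(seed: int = 0, effects=None, **kwargs) -> ie.SynthConfig:
    """A fast, small synthetic study used across tests."""
    defaults = dict(
        fs_raw=512.0,
        epoch_durations={"baseline": 40.0, "ketamine": 40.0, "propofol": 40.0},
        shanks=[
            ie.ShankSpec("sf", 4, "superiorfrontal"),
            ie.ShankSpec("oc", 4, "lateraloccipital"),
            ie.ShankSpec("pc", 3, "posteriorcingulate"),
        ],
        effects=effects if effects is not None else [],
        line_noise=(60.0, 3, (1.0, 0.5, 0.25)),
        n_subjects=1,
        seed=seed,
    )
    defaults.update(kwargs)
    return ie.SynthConfig(**defaults)
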