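"""Multitaper spectral estimation and condition-contrast band power.

The estimator follows the classic Thomson construction: K leading discrete
prolate spheroidal sequences (DPSS) computed from the symmetric tridiagonal
eigenproblem, eigenspectra averaged with uniform weights (no adaptive
weighting), sliding windows of T seconds advanced by ``T - overlap``.
Power is one-sided spectral density in units^2/Hz: interior bins doubled,
DC and Nyquist not, so that the integral of the PSD over [0, Nyquist]
equals the signal variance (Parseval).

Defaults are the study's parameters: T = 2 s, overlap = 0.5 s (step 1.5 s),
NW = 3, K = 5, giving 0.5 Hz grid resolution and half-bandwidth
W = NW/T = 1.5 Hz.  "Overlap" is read literally as seconds of overlap; a
fractional-overlap reading is available via ``overlap_is_fraction``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import Recording, epoch_interval

logger = logging.getLogger(__name__)

__all__ = [
    "TaperSet",
    "SpectralEstimate",
    "BandDef",
    "ConditionPSD",
    "STUDY_BANDS",
    "compute_dpss",
    "multitaper_spectrogram",
    "condition_mean_psd",
    "to_decibels",
    "band_power_change",
]


@dataclass
class TaperSet:
    """K unit-energy orthonormal tapers with concentration eigenvalues."""

    tapers: np.ndarray  # (K, N)
    concentrations: np.ndarray  # (K,), strictly decreasing, in (0, 1)
    n: int
    nw: float
    k: int


@dataclass
class SpectralEstimate:
    """Time-frequency power: (channels x windows x frequencies), units^2/Hz."""

    freqs: np.ndarray
    times: np.ndarray  # window centers, seconds
    power: np.ndarray
    channel_ids: list[str]
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BandDef:
    """Named frequency band, half-open [f_lo, f_hi) on the analysis grid."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0.0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi})")


#: The study's canonical band set plus the posteromedial 3-4 Hz band.
STUDY_BANDS = [
    BandDef("slow", 0.1, 1.0),
    BandDef("delta", 1.0, 4.0),
    BandDef("theta", 4.0, 8.0),
    BandDef("alpha", 8.0, 15.0),
    BandDef("beta", 15.0, 25.0),
    BandDef("gamma", 25.0, 55.0),
    BandDef("low gamma", 25.0, 40.0),
    BandDef("upper gamma", 40.0, 55.0),
    BandDef("3-4 Hz", 3.0, 4.0),
]


@dataclass
class ConditionPSD:
    """Per-channel, per-condition mean PSD stored in dB."""

    freqs: np.ndarray
    conditions: list[str]
    psd_db: np.ndarray  # (channels x conditions x frequencies)
    channel_ids: list[str]


def compute_dpss(N: int, NW: float, K: int) -> TaperSet:
    """Leading K discrete prolate spheroidal sequences of length N.

    Solved from the symmetric tridiagonal matrix whose eigenvectors are the
    DPSS (diagonal ((N-1-2t)/2)^2 cos(2 pi W), off-diagonal t(N-t)/2 with
    W = NW/N); eigenvectors are unit-energy by construction.  Concentration
    eigenvalues (fraction of spectral energy inside [-W, W]) are computed
    from the sinc kernel quadratic form.  Requires K <= 2 NW: higher-order
    tapers are poorly concentrated and rejected.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 2 * NW:
        raise ValueError(f"K={K} exceeds 2*NW={2 * NW}: tapers would be poorly concentrated")
    if N <= K:
        raise ValueError(f"need N > K, got N={N}, K={K}")
    W = NW / N
    t = np.arange(N, dtype=np.float64)
    diag = ((N - 1.0 - 2.0 * t) / 2.0) ** 2 * np.cos(2.0 * np.pi * W)
    off = np.arange(1, N, dtype=np.float64) * (N - np.arange(1, N)) / 2.0
    _, vecs = scipy.linalg.eigh_tridiagonal(diag, off, select="i", select_range=(N - K, N - 1))
    tapers = vecs[:, ::-1].T.copy()  # order by decreasing concentration

    # Sign convention: symmetric tapers have positive mean; antisymmetric
    # ones start on a positive lobe.
    for k in range(K):
        s = tapers[k].sum()
        if abs(s) > 1e-7:
            tapers[k] *= np.sign(s)
        else:
            lead = tapers[k][: N // 2]
            tapers[k] *= np.sign(lead[np.argmax(np.abs(lead))])

    # Concentration lambda_k = v^T A v, A_ij = sin(2 pi W (i-j)) / (pi (i-j)).
    idx = np.arange(N, dtype=np.float64)
    col = np.where(idx == 0, 2.0 * W, np.sin(2.0 * np.pi * W * idx) / (np.pi * np.maximum(idx, 1)))
    A = scipy.linalg.toeplitz(col)
    conc = ((tapers @ A) * tapers).sum(axis=1)

    if not np.all(np.diff(conc) < 0):
        raise RuntimeError("concentrations not strictly decreasing; eigenproblem failed")
    return TaperSet(tapers=tapers, concentrations=conc, n=N, nw=NW, k=K)


def _window_starts(n_samples: int, fs: float, T: float, step: float) -> np.ndarray:
    """Start sample of every full window: i*step seconds, trailing partials dropped."""
    n_win_len = int(round(T * fs))
    duration = n_samples / fs
    n_win = int(np.floor((duration - T) / step)) + 1
    if n_win < 1:
        raise ValueError(f"recording of {duration:.3f} s shorter than window T={T} s")
    starts = np.floor(np.arange(n_win) * step * fs).astype(int)
    return starts[starts + n_win_len <= n_samples]


def multitaper_spectrogram(
    rec: Recording,
    T: float = 2.0,
    overlap: float = 0.5,
    NW: float = 3.0,
    K: int = 5,
    overlap_is_fraction: bool = False,
    tapers: np.ndarray | None = None,
    window_detrend: str = "linear",
) -> SpectralEstimate:
    """Sliding-window multitaper PSD estimate for every channel.

    Per window the estimate is the uniform mean over K tapers of
    |rfft(taper * segment)|^2, scaled to one-sided density.  ``overlap`` is
    seconds of overlap (step = T - overlap); set ``overlap_is_fraction`` to
    read it as a fraction of T instead.  ``tapers`` overrides the DPSS set
    (rows = tapers; used for cross-checking against plain periodograms).

    ``window_detrend`` ('linear', 'mean' or 'none') removes the per-window
    least-squares line (or mean) before tapering: infra-resolution drift
    otherwise leaks through taper sidelobes and lifts the broadband floor.
    """
    if window_detrend not in ("linear", "mean", "none"):
        raise ValueError("window_detrend must be 'linear', 'mean' or 'none'")
    n_win_len = round(rec.fs * T)
    if abs(n_win_len - rec.fs * T) > 1e-9 or n_win_len < 2:
        raise ValueError(f"fs*T = {rec.fs * T} must be a positive integer sample count")
    n_win_len = int(n_win_len)
    if overlap_is_fraction:
        if not 0.0 <= overlap < 1.0:
            raise ValueError("fractional overlap must be in [0, 1)")
        step = T * (1.0 - overlap)
    else:
        if not 0.0 <= overlap < T:
            raise ValueError(f"overlap {overlap} s must be in [0, T={T})")
        step = T - overlap

    if tapers is None:
        taper_set = compute_dpss(n_win_len, NW, K)
        tapers = taper_set.tapers
    else:
        tapers = np.atleast_2d(np.asarray(tapers, dtype=np.float64))
        if tapers.shape[1] != n_win_len:
            raise ValueError("taper length must equal fs*T samples")
        K = tapers.shape[0]

    starts = _window_starts(rec.n_samples, rec.fs, T, step)
    freqs = np.fft.rfftfreq(n_win_len, 1.0 / rec.fs)
    scale = np.full(freqs.size, 2.0 / rec.fs)
    scale[0] = 1.0 / rec.fs
    if n_win_len % 2 == 0:
        scale[-1] = 1.0 / rec.fs

    seg_idx = starts[:, None] + np.arange(n_win_len)[None, :]
    power = np.empty((rec.n_channels, starts.size, freqs.size))
    import scipy.signal as _sig

    for ch in range(rec.n_channels):
        segs = rec.data[ch][seg_idx]  # (windows, N)
        if window_detrend == "linear":
            segs = _sig.detrend(segs, axis=-1, type="linear")
        elif window_detrend == "mean":
            segs = segs - segs.mean(axis=-1, keepdims=True)
        spec = np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)
        power[ch] = (np.abs(spec) ** 2).mean(axis=1) * scale
    times = (starts + n_win_len / 2.0) / rec.fs
    return SpectralEstimate(
        freqs=freqs,
        times=times,
        power=power,
        channel_ids=list(rec.channel_ids),
        params={
            "T": T, "step": step, "overlap": overlap, "NW": NW, "K": K,
            "fs": rec.fs, "window_detrend": window_detrend,
        },
    )


def to_decibels(power: np.ndarray | float, floor_db: float = -300.0) -> np.ndarray:
    """10 log10(power); zeros map to ``floor_db`` with a logged warning."""
    power = np.asarray(power, dtype=np.float64)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    zero = power == 0
    if np.any(zero):
        logger.warning("to_decibels: %d zero power values floored at %g dB", zero.sum(), floor_db)
    out = np.full(power.shape, floor_db)
    np.log10(power, out=out, where=~zero)
    out[~zero] *= 10.0
    return out


def condition_mean_psd(est: SpectralEstimate, epochs: pd.DataFrame) -> ConditionPSD:
    """Average raw window power within each condition, then convert to dB.

    A window belongs to a condition iff it lies entirely inside the
    condition's half-open interval; straddling windows count for neither.
    A condition with zero full windows is an error.
    """
    T = est.params["T"]
    conditions = epochs["condition"].tolist()
    psd = np.empty((est.power.shape[0], len(conditions), est.freqs.size))
    for j, cond in enumerate(conditions):
        start, end = epoch_interval(epochs, cond)
        w0, w1 = est.times - T / 2.0, est.times + T / 2.0
        inside = (w0 >= start - 1e-9) & (w1 <= end + 1e-9)
        if not inside.any():
            raise ValueError(f"condition {cond!r} contains no full analysis window")
        psd[:, j, :] = est.power[:, inside, :].mean(axis=1)
    return ConditionPSD(
        freqs=est.freqs,
        conditions=conditions,
        psd_db=to_decibels(psd),
        channel_ids=list(est.channel_ids),
    )


def band_bins(freqs: np.ndarray, band: BandDef) -> np.ndarray:
    """Boolean mask of grid bins with f in [f_lo, f_hi)."""
    return (freqs >= band.f_lo - 1e-9) & (freqs < band.f_hi - 1e-9)


def band_power_change(
    psd: ConditionPSD,
    band: BandDef,
    cond_b: str,
    cond_a: str,
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-channel dB contrast ``cond_b - cond_a`` aggregated over a band.

    The per-bin dB difference is aggregated over bins in [f_lo, f_hi) by
    ``mode``: 'mean' (mean dB difference per bin, the default) or 'sum'
    (summed over bins).  Returns a DataFrame with one row per channel.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    for cond in (cond_b, cond_a):
        if cond not in psd.conditions:
            raise KeyError(f"condition {cond!r} not in ConditionPSD")
    mask = band_bins(psd.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band.name} [{band.f_lo}, {band.f_hi}) contains no grid bins")
    jb, ja = psd.conditions.index(cond_b), psd.conditions.index(cond_a)
    diff = psd.psd_db[:, jb, mask] - psd.psd_db[:, ja, mask]
    value = diff.mean(axis=1) if mode == "mean" else diff.sum(axis=1)
    return pd.DataFrame(
        {
            "channel": psd.channel_ids,
            "band": band.name,
            "contrast": f"{cond_b}-{cond_a}",
            "value_db": value,
            "mode": mode,
        }
    )
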