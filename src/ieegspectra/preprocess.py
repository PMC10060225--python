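"""Signal conditioning chain for depth-electrode recordings.

Fixed stage order: notch -> resample -> detrend -> channel exclusion ->
bipolar re-referencing.  Each stage is a pure function from Recording (and
channel metadata) to Recording.

Conventions
-----------
* Time intervals are half-open [start, end) seconds; sample index =
  floor(t * fs), 0-based.
* Bipolar derivation pairs adjacent contacts on the same shank (positions
  p and p+1, position 1 = deepest), deeper minus shallower.  An excluded
  contact breaks the chain: pairs never bridge a gap.  The derived channel
  inherits the deeper contact's anatomical label (the common sEEG
  convention; configurable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.signal

from .containers import Recording, validate_channel_table

logger = logging.getLogger(__name__)

__all__ = [
    "notch_filter",
    "resample_to",
    "detrend_full",
    "drop_excluded",
    "bipolar_montage",
    "preprocess_chain",
    "expected_bipolar_count",
]


def _design_notch(f0: float, fs: float):
    """Zero-phase band-stop for one harmonic.

    Chebyshev-II band-stop with stopband f0 +/- 1 Hz and passband edges
    f0 +/- 3 Hz; gains are specified for a single pass, and the filter is
    applied forward-backward (sosfiltfilt), which doubles attenuation in dB
    and cancels group delay.
    """
    wp = [f0 - 3.0, f0 + 3.0]
    ws = [f0 - 1.0, f0 + 1.0]
    n, wn = scipy.signal.cheb2ord(wp, ws, gpass=0.2, gstop=18.0, fs=fs)
    return scipy.signal.cheby2(n, 18.0, wn, btype="bandstop", output="sos", fs=fs)


def notch_filter(rec: Recording, base: float = 60.0, through: float | None = None) -> Recording:
    """Remove line noise at ``base`` Hz and all harmonics up to ``through``.

    ``through`` defaults to Nyquist.  Each harmonic gets its own zero-phase
    band-stop: >= 30 dB attenuation within +/-1 Hz of the harmonic, < 1 dB
    change beyond +/-3 Hz.
    """
    nyq = rec.fs / 2.0
    if base >= nyq:
        raise ValueError(f"notch base {base} Hz >= Nyquist {nyq} Hz")
    if through is None:
        through = nyq
    data = rec.data
    f0 = base
    while f0 <= min(through, nyq - 4.0):  # need passband edge below Nyquist
        sos = _design_notch(f0, rec.fs)
        data = scipy.signal.sosfiltfilt(sos, data, axis=-1)
        f0 += base
    return Recording(np.ascontiguousarray(data), rec.fs, list(rec.channel_ids))


def resample_to(rec: Recording, target_fs: float = 500.0) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs`` Hz.

    The fs ratio must be rational.  ``target_fs == fs`` is the identity
    (so re-running the chain is a no-op); ``target_fs > fs`` is rejected.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds current fs {rec.fs}")
    if target_fs == rec.fs:
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    if not np.isclose(float(frac), target_fs / rec.fs, rtol=0, atol=1e-12):
        raise ValueError(f"fs ratio {target_fs}/{rec.fs} is not rational")
    data = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return Recording(data, target_fs, list(rec.channel_ids))


def detrend_full(rec: Recording) -> Recording:
    """Remove the per-channel least-squares line over the whole recording."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to detrend")
    data = scipy.signal.detrend(rec.data, axis=-1, type="linear")
    return Recording(data, rec.fs, list(rec.channel_ids))


def drop_excluded(
    rec: Recording, channels: pd.DataFrame
) -> tuple[Recording, pd.DataFrame]:
    """Drop contacts flagged ``excluded`` from both recording and table.

    Channel order is preserved.  Every contact in the table must exist in
    the recording; unknown ids raise with the offending id named.
    """
    unknown = [c for c in channels["contact_id"] if c not in set(rec.channel_ids)]
    if unknown:
        raise KeyError(f"channel table references unknown contact ids: {unknown}")
    keep = channels.loc[~channels["excluded"].astype(bool)]
    n_dropped = len(channels) - len(keep)
    if n_dropped:
        logger.info("dropping %d excluded contacts", n_dropped)
    out_rec = rec.pick(keep["contact_id"].tolist())
    return out_rec, keep.reset_index(drop=True)


def _adjacent_pairs(group: pd.DataFrame) -> list[tuple[pd.Series, pd.Series]]:
    """Surviving adjacent (p, p+1) contact pairs on one shank, no bridging."""
    by_pos = {int(r["position"]): r for _, r in group.iterrows()}
    pairs = []
    for p in sorted(by_pos):
        if p + 1 in by_pos:
            pairs.append((by_pos[p], by_pos[p + 1]))
    return pairs


def bipolar_montage(
    rec: Recording, channels: pd.DataFrame, label_from: str = "deeper"
) -> tuple[Recording, pd.DataFrame]:
    """Re-reference to adjacent-pair bipolar derivations per shank.

    Each surviving pair (position p deeper, p+1 shallower) yields one
    derived channel: deeper minus shallower, id ``<subject>:<shank>:p-p+1``,
    anatomical label from the deeper contact (or shallower, if
    ``label_from='shallower'``).  Shanks with fewer than two surviving
    contacts yield no pairs (logged, not an error).
    """
    if label_from not in ("deeper", "shallower"):
        raise ValueError("label_from must be 'deeper' or 'shallower'")
    index = {c: i for i, c in enumerate(rec.channel_ids)}
    rows, traces = [], []
    for (subj, shank), grp in channels.groupby(["subject", "shank_id"], sort=False):
        pairs = _adjacent_pairs(grp)
        if not pairs:
            logger.info("shank %s of %s has <2 surviving contacts: 0 pairs", shank, subj)
            continue
        for deep, shallow in pairs:
            trace = rec.data[index[deep["contact_id"]]] - rec.data[index[shallow["contact_id"]]]
            src = deep if label_from == "deeper" else shallow
            p = int(deep["position"])
            rows.append(
                {
                    "subject": subj,
                    "contact_id": f"{subj}:{shank}:{p}-{p + 1}",
                    "shank_id": shank,
                    "position": p,
                    "fine_label": src["fine_label"],
                    "excluded": False,
                }
            )
            traces.append(trace)
    table = pd.DataFrame(
        rows, columns=["subject", "contact_id", "shank_id", "position", "fine_label", "excluded"]
    )
    data = np.vstack(traces) if traces else np.empty((0, rec.n_samples))
    return Recording(data, rec.fs, table["contact_id"].tolist()), table


def expected_bipolar_count(channels: pd.DataFrame) -> int:
    """Exhaustive count of surviving adjacent same-shank pairs (oracle rule)."""
    keep = channels.loc[~channels["excluded"].astype(bool)]
    n = 0
    for _, grp in keep.groupby(["subject", "shank_id"], sort=False):
        pos = set(int(p) for p in grp["position"])
        n += sum(1 for p in pos if p + 1 in pos)
    return n


def preprocess_chain(
    rec: Recording,
    channels: pd.DataFrame,
    notch_base: float = 60.0,
    target_fs: float = 500.0,
) -> tuple[Recording, pd.DataFrame]:
    """Full conditioning chain in fixed order.

    notch -> resample -> detrend -> drop excluded -> bipolar montage.
    """
    validate_channel_table(channels)
    rec = notch_filter(rec, base=notch_base)
    rec = resample_to(rec, target_fs)
    rec = detrend_full(rec)
    rec, channels = drop_excluded(rec, channels)
    return bipolar_montage(rec, channels)
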