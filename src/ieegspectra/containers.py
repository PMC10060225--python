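"""Core in-memory containers shared by every pipeline stage.

A :class:`Recording` is a plain (channels x samples) float array with a
sampling rate and ordered channel ids.  Channel metadata and epoch
definitions are pandas DataFrames with fixed schemas, validated here so
that every stage can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a channel-metadata table.
CHANNEL_COLUMNS = ["subject", "contact_id", "shank_id", "position", "fine_label", "excluded"]

#: Required columns of an epoch table (half-open [start_s, end_s) intervals).
EPOCH_COLUMNS = ["condition", "start_s", "end_s"]


@dataclass
class Recording:
    """Multi-channel sampled signal.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), signal units (uV for iEEG).
    fs
        Sampling rate in Hz.
    channel_ids
        Ordered unique channel identifiers, one per data row.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.data.shape[1] / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channel_ids))

    def pick(self, channel_ids: list[str]) -> "Recording":
        """Sub-recording restricted to ``channel_ids`` (order preserved as given)."""
        index = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in channel_ids if c not in index]
        if missing:
            raise KeyError(f"unknown channel ids: {missing}")
        rows = [index[c] for c in channel_ids]
        return Recording(self.data[rows], self.fs, list(channel_ids))


def validate_channel_table(channels: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a channel table; returns it unchanged.

    Invariants: required columns present, (subject, shank_id, position)
    unique, positions contiguous (1..n) along each shank.
    """
    missing = [c for c in CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    key = channels[["subject", "shank_id", "position"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (subject, shank, position): {dup}")
    for (subj, shank), grp in channels.groupby(["subject", "shank_id"], sort=False):
        pos = np.sort(grp["position"].to_numpy())
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(
                f"positions on shank {shank} of subject {subj} are not contiguous 1..n: {pos}"
            )
    return channels


def validate_epoch_table(epochs: pd.DataFrame, min_duration: float = 0.0) -> pd.DataFrame:
    """Check epoch intervals are ordered, non-overlapping and long enough."""
    missing = [c for c in EPOCH_COLUMNS if c not in epochs.columns]
    if missing:
        raise ValueError(f"epoch table missing columns: {missing}")
    ep = epochs.sort_values("start_s").reset_index(drop=True)
    if (ep["end_s"] - ep["start_s"] < min_duration).any():
        bad = ep[ep["end_s"] - ep["start_s"] < min_duration]["condition"].tolist()
        raise ValueError(f"epochs shorter than {min_duration} s: {bad}")
    if (ep["start_s"].to_numpy()[1:] < ep["end_s"].to_numpy()[:-1]).any():
        raise ValueError("epoch intervals overlap")
    return epochs


def epoch_interval(epochs: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Half-open [start, end) interval in seconds for one condition."""
    row = epochs[epochs["condition"] == condition]
    if len(row) == 0:
        raise KeyError(f"condition {condition!r} not in epoch table")
    if len(row) > 1:
        raise ValueError(f"condition {condition!r} appears {len(row)} times")
    return float(row["start_s"].iloc[0]), float(row["end_s"].iloc[0])
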