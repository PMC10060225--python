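"""Readers and writers for the pipeline's on-disk formats.

Signals: EDF (read via mne; written by a minimal 16-bit writer) and an
HDF5 container — datasets ``data`` (channels x samples, float64),
attribute ``fs``, dataset ``channel_ids`` (UTF-8 strings) — which keeps
full float precision for synthetic ground-truth data.  Tables (channels,
epochs, label maps, contrasts, summaries) are TSV via pandas; configs are
YAML; spectral estimates are HDF5 (freqs, times, power, params).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import Recording
from .spectral import SpectralEstimate

__all__ = [
    "write_recording",
    "write_recording_edf",
    "read_recording",
    "write_table",
    "read_channel_table",
    "read_epoch_table",
    "write_spectral_estimate",
    "read_spectral_estimate",
    "load_config",
    "dump_config",
]


def write_recording(rec: Recording, path) -> None:
    """Persist a Recording; format chosen by suffix (.edf or .h5/.hdf5)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        write_recording_edf(rec, path)
        return
    if suffix not in (".h5", ".hdf5"):
        raise ValueError(f"unsupported recording format: {path.name}")
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=rec.data)
        ds.attrs["units"] = "uV"
        f.attrs["fs"] = rec.fs
        f.create_dataset(
            "channel_ids", data=np.array(rec.channel_ids, dtype=h5py.string_dtype())
        )


def write_recording_edf(rec: Recording, path) -> None:
    """Write a Recording as EDF (16-bit, 1-second data records, unit uV).

    Minimal but standard-conforming writer: sampling rate must be an
    integer (samples per 1 s record); a trailing partial second is
    truncated; per-channel physical range is taken from the data, so the
    quantization step is (max - min) / 65535.  Channel labels are clipped
    to EDF's 16 characters.
    """
    spr = int(round(rec.fs))
    if abs(spr - rec.fs) > 1e-9 or spr < 1:
        raise ValueError(f"EDF needs an integer sampling rate, got {rec.fs}")
    n_ch = rec.n_channels
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * spr]

    def f8(x: float) -> str:
        return f"{x:.6g}"[:8]

    pmin = np.array([float(f8(v)) for v in np.minimum(data.min(axis=1), 0) - 1e-6])
    pmax = np.array([float(f8(v)) for v in np.maximum(data.max(axis=1), 0) + 1e-6])
    dmin, dmax = -32768, 32767

    def field(vals, width: int) -> bytes:
        return b"".join(str(v).encode("ascii")[:width].ljust(width) for v in vals)

    hdr = b"0".ljust(8)
    hdr += b"X".ljust(80) + b"X".ljust(80)
    hdr += b"01.01.00" + b"00.00.00"
    hdr += str(256 * (1 + n_ch)).encode().ljust(8)
    hdr += b" " * 44
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(n_ch).encode().ljust(4)
    hdr += field(rec.channel_ids, 16)
    hdr += field([""] * n_ch, 80)  # transducer
    hdr += field(["uV"] * n_ch, 8)
    hdr += field([f8(v) for v in pmin], 8)
    hdr += field([f8(v) for v in pmax], 8)
    hdr += field([dmin] * n_ch, 8)
    hdr += field([dmax] * n_ch, 8)
    hdr += field([""] * n_ch, 80)  # prefiltering
    hdr += field([spr] * n_ch, 8)
    hdr += field([""] * n_ch, 32)
    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            block = data[:, r * spr : (r + 1) * spr]
            dig = np.round((block - pmin[:, None]) * scale[:, None] + dmin)
            f.write(dig.astype("<i2").tobytes())


def _read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_ids"][()]]
    return Recording(data, fs, ids)


def _read_recording_edf(path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # EDF channels carry uV; mne rescales to SI volts internally.
    return Recording(raw.get_data(units="uV"), float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path) -> Recording:
    """Load a Recording from EDF (.edf) or the HDF5 container (.h5/.hdf5)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return _read_recording_edf(path)
    if suffix in (".h5", ".hdf5"):
        return _read_recording_h5(path)
    raise ValueError(f"unsupported recording format: {path.name}")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_channel_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "contact_id": str, "shank_id": str})
    df["excluded"] = df["excluded"].astype(bool)
    return df


def read_epoch_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"condition": str})


def write_spectral_estimate(est: SpectralEstimate, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=est.freqs)
        f.create_dataset("times", data=est.times)
        f.create_dataset("power", data=est.power)
        f.create_dataset(
            "channel_ids", data=np.array(est.channel_ids, dtype=h5py.string_dtype())
        )
        f.attrs["params"] = json.dumps(est.params)


def read_spectral_estimate(path) -> SpectralEstimate:
    with h5py.File(path, "r") as f:
        return SpectralEstimate(
            freqs=f["freqs"][()],
            times=f["times"][()],
            power=f["power"][()],
            channel_ids=[
                c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_ids"][()]
            ],
            params=json.loads(f.attrs["params"]),
        )


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
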