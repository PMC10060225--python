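"""Synthetic multi-subject sEEG study generator with known injected effects.

Emulates the signal structure of a depth-electrode anesthesia study:
2 kHz sampling, multi-shank montage, 1/f background, 60 Hz line noise with
harmonics, and condition-dependent band-limited power changes localized to
anatomical regions.  Every injected effect is known exactly, so the full
analysis pipeline (preprocessing -> multitaper spectrogram -> band-power
contrast -> ROI bootstrap) can be validated against ground truth.

Effects are realized by scaling the segment's own band content: the
signal's zero-phase FFT-masked band component is multiplied by a gain
solved from the target dB change, which leaves out-of-band power exactly
invariant and handles both increases and decreases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "ShankSpec",
    "SynthConfig",
    "default_shanks",
    "default_effects",
    "make_background",
    "inject_band_effect",
    "generate_subject",
    "generate_study",
    "iter_subjects",
]


@dataclass(frozen=True)
class EffectSpec:
    """A condition-dependent band-power change injected into one region.

    ``roi`` may be a fine (DKT) label or a coarse group name from the
    shipped 15-group map; ``delta_db`` is the target band-power change in
    dB relative to that channel's own baseline.
    """

    condition: str
    roi: str
    band: tuple[float, float]
    delta_db: float


@dataclass(frozen=True)
class ShankSpec:
    """One depth-electrode shank: id, contact count and per-contact labels.

    ``labels`` is either a single fine label applied to every contact or a
    sequence with one label per contact (position 1 = deepest).
    """

    shank_id: str
    n_contacts: int
    labels: str | tuple[str, ...]

    def contact_labels(self) -> list[str]:
        if isinstance(self.labels, str):
            return [self.labels] * self.n_contacts
        if len(self.labels) != self.n_contacts:
            raise ValueError(
                f"shank {self.shank_id}: {len(self.labels)} labels for "
                f"{self.n_contacts} contacts"
            )
        return list(self.labels)


def default_shanks() -> list[ShankSpec]:
    """Default montage: 10 shanks x 10 contacts covering the study's ROIs."""
    labels = [
        "superiorfrontal",
        "rostralmiddlefrontal",
        "parsopercularis",
        "precentral",
        "postcentral",
        "posteriorcingulate",
        "isthmuscingulate",
        "superiortemporal",
        "lateraloccipital",
        "hippocampus",
    ]
    return [ShankSpec(f"s{i + 1:02d}", 10, lab) for i, lab in enumerate(labels)]


def default_effects() -> list[EffectSpec]:
    """Default effect topography: the qualitative drug-condition pattern.

    Frontal gamma rises under ketamine and reverts under propofol (no
    propofol injection, so the propofol-ketamine contrast is negative);
    occipital alpha falls under ketamine and falls further under propofol;
    the posteromedial 3-4 Hz rhythm rises under ketamine and rises further
    (additively) under propofol.  Magnitudes are generator choices; see the
    methods note.
    """
    return [
        EffectSpec("ketamine", "sup frontal", (25.0, 55.0), +10.0),
        EffectSpec("ketamine", "occipital", (8.0, 15.0), -8.0),
        EffectSpec("propofol", "occipital", (8.0, 15.0), -16.0),
        EffectSpec("ketamine", "posteriorcingulate", (3.0, 4.0), +6.0),
        EffectSpec("propofol", "posteriorcingulate", (3.0, 4.0), +12.0),
        EffectSpec("ketamine", "isthmuscingulate", (3.0, 4.0), +6.0),
        EffectSpec("propofol", "isthmuscingulate", (3.0, 4.0), +12.0),
    ]


@dataclass
class SynthConfig:
    """Full description of a synthetic study.

    Defaults follow the study design: 2000 Hz raw sampling, epochs of
    300 s baseline / 840 s ketamine / 235 s propofol, 10 subjects with
    10 shanks x 10 contacts each.
    """

    fs_raw: float = 2000.0
    epoch_durations: dict[str, float] = field(
        default_factory=lambda: {"baseline": 300.0, "ketamine": 840.0, "propofol": 235.0}
    )
    shanks: list[ShankSpec] = field(default_factory=default_shanks)
    background: tuple[float, float] = (1.5, 1.0)  # (1/f exponent beta, variance)
    line_noise: tuple[float, int, tuple[float, ...]] = (60.0, 3, (2.0, 0.8, 0.4))
    effects: list[EffectSpec] = field(default_factory=default_effects)
    artifact_channels: list[str] = field(default_factory=list)
    n_subjects: int = 10
    seed: int = 0
    ramp_s: float = 0.0  # optional cosine ramp at effect onset/offset
    min_epoch_s: float = 2.0  # shortest epoch the estimator window allows
    background_knee_hz: float = 1.0  # low-frequency flattening of the aperiodic background
    # Effects are injected with this margin beyond the nominal band edges so
    # that a multitaper estimator with half-bandwidth W sees every nominal
    # band bin fully scaled; defaults to the study estimator's W = NW/T.
    effect_edge_margin_hz: float = 1.5

    def validate(self) -> None:
        if self.fs_raw <= 0:
            raise ValueError("fs_raw must be positive")
        nyq = self.fs_raw / 2.0
        base, n_harm, amps = self.line_noise
        if len(amps) != n_harm:
            raise ValueError("line_noise amplitudes must match harmonic count")
        top = max([base * n_harm] + [eff.band[1] for eff in self.effects])
        if self.fs_raw <= 2.0 * top:
            raise ValueError(
                f"fs_raw={self.fs_raw} must exceed twice the highest injected "
                f"frequency ({top} Hz)"
            )
        for cond, dur in self.epoch_durations.items():
            if dur < self.min_epoch_s:
                raise ValueError(
                    f"epoch {cond!r} of {dur} s is shorter than the analysis window "
                    f"({self.min_epoch_s} s)"
                )
        for eff in self.effects:
            lo, hi = eff.band
            if not (0.0 < lo < hi < nyq):
                raise ValueError(f"effect band {eff.band} outside (0, Nyquist={nyq})")
            if not np.isfinite(eff.delta_db):
                raise ValueError("effect delta_db must be finite")
        beta, var = self.background
        if beta < 0:
            raise ValueError("background 1/f exponent must be >= 0")
        if var <= 0:
            raise ValueError("background variance must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def make_background(
    n_samples: int,
    beta: float,
    variance: float,
    seed: int | np.random.Generator,
    fs: float = 2000.0,
    knee_hz: float = 0.5,
) -> np.ndarray:
    """Zero-mean aperiodic (1/f^beta) noise with a low-frequency knee.

    White Gaussian noise is spectrally shaped to power
    ``(f^2 + knee^2)^(-beta/2)``: slope -beta on log-log axes above the
    knee, flat below it.  The knee emulates the low-frequency flattening of
    AC-coupled intracranial recordings; without it an arbitrarily large
    share of the variance would sit below any estimator's resolution and
    appear only as broadband taper leakage.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if knee_hz < 0:
        raise ValueError("knee_hz must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    if knee_hz > 0:
        shaping = (f**2 + knee_hz**2) ** (-beta / 4.0)
    else:
        shaping = np.ones(f.size)
        shaping[1:] = f[1:] ** (-beta / 2.0)
    shaping[0] = 0.0  # DC zeroed -> exact zero mean
    x = np.fft.irfft(spec * shaping, n_samples)
    sd = x.std()
    if sd > 0:
        x *= np.sqrt(variance) / sd
    return x


def _cosine_ramp_envelope(n: int, n_ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset of ``n_ramp`` samples."""
    env = np.ones(n)
    n_ramp = min(n_ramp, n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[n - n_ramp:] = ramp[::-1]
    return env


def inject_band_effect(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float],
    delta_db: float,
    interval: tuple[float, float],
    ramp_s: float = 0.0,
) -> np.ndarray:
    """Scale band power inside ``interval`` by ``10**(delta_db/10)``.

    The segment's band component (zero-phase ideal FFT-mask bandpass over
    half-open [f_lo, f_hi)) is scaled by ``10**(delta_db/20) - 1`` and added
    back, so in-band power changes by exactly the target ratio while
    out-of-band power is untouched.  A raised-cosine ramp of ``ramp_s``
    seconds (optional) smooths the effect onset/offset.

    Returns a modified copy; the input is not mutated.
    """
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band {band} must lie strictly inside (0, Nyquist={fs / 2.0})")
    if not np.isfinite(delta_db):
        raise ValueError("delta_db must be finite")
    t0, t1 = interval
    i0, i1 = int(np.floor(t0 * fs)), int(np.floor(t1 * fs))
    if not (0 <= i0 < i1 <= signal.size):
        raise ValueError(f"interval {interval} outside signal of {signal.size / fs:.3f} s")
    out = signal.astype(np.float64, copy=True)
    gain = 10.0 ** (delta_db / 20.0) - 1.0
    if gain == 0.0:
        return out
    seg = out[i0:i1]
    freqs = np.fft.rfftfreq(seg.size, 1.0 / fs)
    spec = np.fft.rfft(seg)
    mask = (freqs >= lo) & (freqs < hi)
    band_component = np.fft.irfft(spec * mask, seg.size)
    env = _cosine_ramp_envelope(seg.size, int(round(ramp_s * fs)))
    out[i0:i1] = seg + gain * env * band_component
    return out


def _build_channel_table(cfg: SynthConfig, subject: str) -> pd.DataFrame:
    rows = []
    for shank in cfg.shanks:
        for pos, label in enumerate(shank.contact_labels(), start=1):
            cid = f"{subject}:{shank.shank_id}:{pos}"
            short = f"{shank.shank_id}:{pos}"
            excluded = cid in cfg.artifact_channels or short in cfg.artifact_channels
            rows.append(
                {
                    "subject": subject,
                    "contact_id": cid,
                    "shank_id": shank.shank_id,
                    "position": pos,
                    "fine_label": label,
                    "excluded": bool(excluded),
                }
            )
    return pd.DataFrame(rows)


def _epoch_table(cfg: SynthConfig) -> pd.DataFrame:
    rows, t = [], 0.0
    for cond, dur in cfg.epoch_durations.items():
        rows.append({"condition": cond, "start_s": t, "end_s": t + dur})
        t += dur
    return pd.DataFrame(rows)


def _matches_roi(fine_label: str, roi: str, coarse_of: dict[str, str]) -> bool:
    return fine_label == roi or coarse_of.get(fine_label) == roi


def generate_subject(
    cfg: SynthConfig, subject_index: int
) -> tuple[Recording, pd.DataFrame, pd.DataFrame, set[int]]:
    """Generate one subject's recording, channel table and epoch table.

    The per-subject RNG is derived from the master seed and the subject
    counter, so subjects are independent yet the whole study is exactly
    reproducible.  Returns additionally the set of effect indices realized
    on at least one contact of this subject.
    """
    from .roi import load_label_map  # local import: roi module is independent of us

    cfg.validate()
    subject = f"sub{subject_index + 1:02d}"
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), subject_index]))
    channels = _build_channel_table(cfg, subject)
    epochs = _epoch_table(cfg)
    n = int(round(sum(cfg.epoch_durations.values()) * cfg.fs_raw))
    beta, var = cfg.background

    # Line noise is common-mode across the montage (one set of phases per subject).
    base, n_harm, amps = cfg.line_noise
    t = np.arange(n) / cfg.fs_raw
    line = np.zeros(n)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)
    for h in range(n_harm):
        line += amps[h] * np.sin(2.0 * np.pi * base * (h + 1) * t + phases[h])

    coarse_of = load_label_map("15").mapping
    cond_interval = {
        row.condition: (row.start_s, row.end_s) for row in epochs.itertuples()
    }

    data = np.empty((len(channels), n))
    realized: set[int] = set()
    margin = cfg.effect_edge_margin_hz
    for row_i, row in enumerate(channels.itertuples()):
        x = make_background(n, beta, var, rng, fs=cfg.fs_raw, knee_hz=cfg.background_knee_hz)
        for eff_i, eff in enumerate(cfg.effects):
            if eff.condition not in cond_interval:
                continue
            if _matches_roi(row.fine_label, eff.roi, coarse_of):
                lo = max(eff.band[0] - margin, 0.25 * eff.band[0])
                hi = min(eff.band[1] + margin, 0.49 * cfg.fs_raw)
                x = inject_band_effect(
                    x, cfg.fs_raw, (lo, hi), eff.delta_db,
                    cond_interval[eff.condition], ramp_s=cfg.ramp_s,
                )
                realized.add(eff_i)
        x += line
        if row.excluded:  # artifact channel: drown it in broadband noise
            x += rng.standard_normal(n) * np.sqrt(25.0 * var)
        data[row_i] = x

    rec = Recording(data, cfg.fs_raw, channels["contact_id"].tolist())
    return rec, channels, epochs, realized


def iter_subjects(cfg: SynthConfig):
    """Yield (Recording, ChannelTable, EpochTable) per subject, memory-lean."""
    for i in range(cfg.n_subjects):
        rec, channels, epochs, _ = generate_subject(cfg, i)
        yield rec, channels, epochs


def generate_study(cfg: SynthConfig) -> tuple[Recording, pd.DataFrame, pd.DataFrame]:
    """Generate the whole study as one stacked Recording.

    All subjects share the epoch clock, so their channels are stacked into
    a single Recording (contact ids are subject-prefixed).  Effects whose
    ROI matches no contact, or whose condition is absent from the epoch
    table, are reported with a warning as unrealized.  For full-scale
    configurations prefer :func:`iter_subjects`, which does not hold every
    subject in memory at once.
    """
    cfg.validate()
    recs, tables, realized_all = [], [], set()
    epochs = _epoch_table(cfg)
    for i in range(cfg.n_subjects):
        rec, channels, _, realized = generate_subject(cfg, i)
        recs.append(rec)
        tables.append(channels)
        realized_all |= realized
    unrealized = [
        cfg.effects[i] for i in range(len(cfg.effects)) if i not in realized_all
    ]
    for eff in unrealized:
        warnings.warn(
            f"effect {eff} matched no contact (or its condition has no epoch); "
            "left unrealized",
            stacklevel=2,
        )
    data = np.vstack([r.data for r in recs])
    ids = [c for r in recs for c in r.channel_ids]
    return Recording(data, cfg.fs_raw, ids), pd.concat(tables, ignore_index=True), epochs
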