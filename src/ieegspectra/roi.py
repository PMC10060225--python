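"""Anatomical grouping and bootstrap statistics for band-power contrasts.

Fine DKT parcellation labels are grouped into coarse regions by a shipped
editable TSV map (15 groups for the ketamine analysis, 14 — without
striatum — for the propofol analysis).  Per (ROI, band, contrast) the
channel contrasts pooled across subjects get a percentile-bootstrap 95%
confidence interval around the mean, resampling channels with replacement;
a region is classified "increase"/"decrease" only when the whole interval
lies off zero, otherwise "no_change".  No multiple-comparison correction
is applied — the analysis reports effect sizes with CIs, not p-values —
and this is recorded in the output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectral import ConditionPSD

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "ROISummary",
    "load_label_map",
    "map_to_coarse",
    "bootstrap_roi_ci",
    "classify_change",
    "roi_spectrum",
    "summarize_rois",
]


@dataclass(frozen=True)
class LabelMap:
    """Mapping from fine parcellation labels to coarse group names."""

    name: str
    mapping: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)


def load_label_map(which: str = "15") -> LabelMap:
    """Load a shipped label map: '15' (with striatum) or '14' (without)."""
    if which not in ("15", "14"):
        raise ValueError("which must be '15' or '14'")
    ref = resources.files("ieegspectra.data") / f"labelmap_{which}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return LabelMap(name=f"{which}-group", mapping=dict(zip(df["fine_label"], df["coarse_label"])))


def read_label_map(path, name: str | None = None) -> LabelMap:
    """Read a user-edited (fine_label, coarse_label) TSV."""
    df = pd.read_csv(path, sep="\t")
    return LabelMap(name=name or str(path), mapping=dict(zip(df["fine_label"], df["coarse_label"])))


def map_to_coarse(channels: pd.DataFrame, label_map: LabelMap) -> pd.DataFrame:
    """Annotate channels with a ``coarse_label`` column.

    Channels whose fine label is absent from the map are dropped with a
    logged count (they are reported, not an error).
    """
    out = channels.copy()
    out["coarse_label"] = out["fine_label"].map(label_map.mapping)
    unmapped = out["coarse_label"].isna()
    if unmapped.any():
        labels = sorted(out.loc[unmapped, "fine_label"].unique())
        logger.warning(
            "dropping %d channels with fine labels absent from %s map: %s",
            int(unmapped.sum()), label_map.name, labels,
        )
    return out.loc[~unmapped].reset_index(drop=True)


@dataclass
class ROISummary:
    """Bootstrap summary of one (ROI, band, contrast) cell."""

    roi: str
    band: str
    contrast: str
    mean: float
    ci_lo: float
    ci_hi: float
    n_channels: int
    n_subjects: int
    classification: str
    n_boot: int
    seed: int


def classify_change(ci_lo: float, ci_hi: float) -> str:
    """'increase' iff CI entirely above 0, 'decrease' iff below, else 'no_change'."""
    if ci_lo > 0.0:
        return "increase"
    if ci_hi < 0.0:
        return "decrease"
    return "no_change"


def _bootstrap_mean_ci(
    values: np.ndarray, n_boot: int, level: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile CI of the mean, resampling rows with replacement."""
    n = values.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    lo, hi = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    qlo, qhi = np.percentile(means, [lo, hi], axis=0)
    return qlo, qhi


def bootstrap_roi_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    roi: str = "",
    band: str = "",
    contrast: str = "",
    subjects: np.ndarray | None = None,
    resample_unit: str = "channel",
) -> ROISummary:
    """Channel-pooled mean and percentile bootstrap CI for one ROI cell.

    ``values`` are per-channel dB contrasts pooled across subjects.  The
    resampling unit is the channel (default); ``resample_unit='subject'``
    resamples whole subjects instead (requires ``subjects``).  Deterministic
    given ``seed``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty value set")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    if resample_unit == "channel":
        ci_lo, ci_hi = _bootstrap_mean_ci(values, n_boot, level, rng)
    elif resample_unit == "subject":
        if subjects is None:
            raise ValueError("subject resampling requires per-value subject ids")
        subjects = np.asarray(subjects)
        uniq = np.unique(subjects)
        groups = [values[subjects == s] for s in uniq]
        picks = rng.integers(0, len(groups), size=(n_boot, len(groups)))
        means = np.array(
            [np.concatenate([groups[g] for g in row]).mean() for row in picks]
        )
        lo, hi = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
        ci_lo, ci_hi = np.percentile(means, [lo, hi])
    else:
        raise ValueError("resample_unit must be 'channel' or 'subject'")
    mean = float(values.mean())
    n_subjects = int(len(np.unique(subjects))) if subjects is not None else 1
    return ROISummary(
        roi=roi,
        band=band,
        contrast=contrast,
        mean=mean,
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        n_channels=int(values.size),
        n_subjects=n_subjects,
        classification=classify_change(float(ci_lo), float(ci_hi)),
        n_boot=n_boot,
        seed=seed,
    )


def summarize_rois(
    contrasts: pd.DataFrame,
    channels: pd.DataFrame,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    resample_unit: str = "channel",
) -> pd.DataFrame:
    """Bootstrap every (coarse ROI, band, contrast) cell of a contrast table.

    ``contrasts`` has columns (channel, band, contrast, value_db, mode) as
    produced by :func:`ieegspectra.spectral.band_power_change`;
    ``channels`` must carry ``coarse_label`` (see :func:`map_to_coarse`).
    Each cell gets its own seed derived deterministically from ``seed``.
    """
    contrasts = contrasts.drop(columns=["subject"], errors="ignore")
    merged = contrasts.merge(
        channels[["contact_id", "subject", "coarse_label"]],
        left_on="channel",
        right_on="contact_id",
        how="inner",
    )
    rows = []
    cells = sorted(
        merged.groupby(["coarse_label", "band", "contrast"], sort=False).groups.keys()
    )
    for i, (roi_name, band_name, contrast_name) in enumerate(cells):
        grp = merged[
            (merged["coarse_label"] == roi_name)
            & (merged["band"] == band_name)
            & (merged["contrast"] == contrast_name)
        ]
        summary = bootstrap_roi_ci(
            grp["value_db"].to_numpy(),
            n_boot=n_boot,
            level=level,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
            roi=roi_name,
            band=band_name,
            contrast=contrast_name,
            subjects=grp["subject"].to_numpy(),
            resample_unit=resample_unit,
        )
        rows.append(vars(summary))
    out = pd.DataFrame(rows)
    out.attrs["multiple_comparison_correction"] = "none (effect sizes with CIs, no p-values)"
    return out


def roi_spectrum(
    psd: ConditionPSD,
    channel_ids: list[str],
    cond_b: str,
    cond_a: str,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frequency channel-pooled dB contrast with bootstrap CI.

    Restricted to ``channel_ids`` (an ROI's channels, pooled across
    subjects); at each grid frequency the mean of per-channel dB
    differences (cond_b - cond_a) and its percentile bootstrap CI are
    returned.  One channel gives a degenerate CI at its own spectrum.
    """
    if len(channel_ids) == 0:
        raise ValueError("ROI channel set is empty")
    index = {c: i for i, c in enumerate(psd.channel_ids)}
    missing = [c for c in channel_ids if c not in index]
    if missing:
        raise KeyError(f"channels not in ConditionPSD: {missing}")
    for cond in (cond_b, cond_a):
        if cond not in psd.conditions:
            raise KeyError(f"condition {cond!r} not in ConditionPSD")
    rows = [index[c] for c in channel_ids]
    jb, ja = psd.conditions.index(cond_b), psd.conditions.index(cond_a)
    diff = psd.psd_db[rows, jb, :] - psd.psd_db[rows, ja, :]  # (channels, freqs)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diff.shape[0], size=(n_boot, diff.shape[0]))
    boot_means = diff[idx].mean(axis=1)  # (n_boot, freqs)
    lo, hi = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    ci = np.percentile(boot_means, [lo, hi], axis=0)
    return pd.DataFrame(
        {
            "freq_hz": psd.freqs,
            "mean_db": diff.mean(axis=0),
            "ci_lo_db": ci[0],
            "ci_hi_db": ci[1],
            "n_channels": diff.shape[0],
            "contrast": f"{cond_b}-{cond_a}",
        }
    )
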