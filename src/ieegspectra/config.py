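"""YAML config parsing: plain dicts -> validated dataclass configs.

The YAML schema mirrors :class:`~ieegspectra.pipeline.RunConfig`; a
``synth`` block mirrors :class:`~ieegspectra.synthetic.SynthConfig`
(``shanks`` as [shank_id, n_contacts, label] triples, ``effects`` as
{condition, roi, band: [lo, hi], delta_db} mappings).  Unknown keys are
rejected so typos fail loudly.  Omitted keys keep the study defaults.
"""

from __future__ import annotations

from dataclasses import fields

from .pipeline import RunConfig
from .spectral import BandDef
from .synthetic import EffectSpec, ShankSpec, SynthConfig

__all__ = ["synth_config_from_dict", "run_config_from_dict"]


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


def synth_config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    _check_keys(d, {f.name for f in fields(SynthConfig)}, "synth")
    if "shanks" in d:
        d["shanks"] = [
            ShankSpec(str(s[0]), int(s[1]), s[2] if isinstance(s[2], str) else tuple(s[2]))
            for s in d["shanks"]
        ]
    if "effects" in d:
        d["effects"] = [
            EffectSpec(
                condition=e["condition"],
                roi=e["roi"],
                band=(float(e["band"][0]), float(e["band"][1])),
                delta_db=float(e["delta_db"]),
            )
            for e in d["effects"]
        ]
    if "line_noise" in d:
        base, n_harm, amps = d["line_noise"]
        d["line_noise"] = (float(base), int(n_harm), tuple(float(a) for a in amps))
    if "background" in d:
        d["background"] = tuple(float(v) for v in d["background"])
    cfg = SynthConfig(**d)
    cfg.validate()
    return cfg


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    _check_keys(d, {f.name for f in fields(RunConfig)}, "run")
    if "synth" in d and d["synth"] is not None:
        d["synth"] = synth_config_from_dict(d["synth"])
    if "bands" in d:
        d["bands"] = [BandDef(str(b[0]), float(b[1]), float(b[2])) for b in d["bands"]]
    if "contrasts" in d:
        d["contrasts"] = [(str(b), str(a)) for b, a in d["contrasts"]]
    if "recordings" in d:
        d["recordings"] = [(str(r), str(c)) for r, c in d["recordings"]]
    if "roi_spectrum_labels" in d:
        d["roi_spectrum_labels"] = tuple(str(x) for x in d["roi_spectrum_labels"])
    cfg = RunConfig(**d)
    cfg.validate()
    return cfg
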