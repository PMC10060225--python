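"""Generate a small synthetic sEEG study and verify an injected effect.

Builds a one-subject study with a -12 dB occipital alpha suppression under
ketamine, then measures the raw-trace band-power contrast with a plain
Welch periodogram to show the generator realizes the requested change.
"""

import numpy as np
import scipy.signal

import ieegspectra as ie

cfg = ie.SynthConfig(
    fs_raw=1024.0,
    epoch_durations={"baseline": 120.0, "ketamine": 120.0},
    shanks=[
        ie.ShankSpec("oc", 4, "lateraloccipital"),
        ie.ShankSpec("sf", 4, "superiorfrontal"),
    ],
    effects=[ie.EffectSpec("ketamine", "occipital", (8.0, 15.0), -12.0)],
    n_subjects=1,
    seed=42,
)
rec, channels, epochs, _ = ie.generate_subject(cfg, 0)
print(f"{rec.n_channels} contacts, {rec.duration:.0f} s at {rec.fs:.0f} Hz")
print(epochs.to_string(index=False))


def alpha_power(x, sl):
    f, p = scipy.signal.welch(x[sl], fs=cfg.fs_raw, nperseg=8192)
    return p[(f >= 8.5) & (f < 14.5)].sum()


base = slice(0, int(120 * cfg.fs_raw))
ket = slice(int(120 * cfg.fs_raw), None)
occ = rec.data[0]  # an occipital contact
sf = rec.data[4]  # a frontal contact
print(
    "occipital alpha contrast: "
    f"{10 * np.log10(alpha_power(occ, ket) / alpha_power(occ, base)):+.2f} dB "
    "(injected -12.00 dB)"
)
print(
    "frontal   alpha contrast: "
    f"{10 * np.log10(alpha_power(sf, ket) / alpha_power(sf, base)):+.2f} dB "
    "(no effect injected)"
)
# The occipital contrast sits within ~0.5 dB of the injected -12 dB while
# the frontal control channel stays near 0 dB: effects are region-specific.
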