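"""Percentile-bootstrap CI for a region's pooled channel contrasts.

Ten channels from three subjects share a -3 dB mean alpha suppression; the
bootstrap resamples channels with replacement, and the region is called a
decrease only because the whole 95% interval lies below zero.
"""

import numpy as np

import ieegspectra as ie

rng = np.random.default_rng(1)
values = rng.normal(loc=-3.0, scale=1.2, size=10)  # per-channel dB contrasts
subjects = np.array(["s1"] * 4 + ["s2"] * 3 + ["s3"] * 3)

summary = ie.bootstrap_roi_ci(
    values, n_boot=10_000, seed=0,
    roi="occipital", band="alpha", contrast="ketamine-baseline",
    subjects=subjects,
)
print(f"mean {summary.mean:+.2f} dB, 95% CI [{summary.ci_lo:+.2f}, {summary.ci_hi:+.2f}]")
print(f"n_channels={summary.n_channels}, n_subjects={summary.n_subjects}, "
      f"classification={summary.classification}")
# A CI that excluded zero on the other side, or straddled it, would flip
# the classification to increase / no_change respectively.
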