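# Methods

## Signal model and preprocessing

A recording is a channels × samples array at sampling rate `fs` (2000 Hz
raw by default).  Conditions are half-open intervals `[start, end)` in
seconds on the recording clock; the sample of time `t` is `floor(t·fs)`,
0-based.  The conditioning chain runs in a fixed order:

1. **Notch.**  One zero-phase Chebyshev-II band-stop per line harmonic
   (60, 120, … Hz up to Nyquist): stopband `f0 ± 1` Hz, passband edges
   `f0 ± 3` Hz, designed for 18 dB stopband / 0.2 dB passband ripple per
   pass and applied forward–backward (`sosfiltfilt`), which doubles the dB
   attenuation and cancels group delay.  Measured: ≥ 30 dB attenuation
   within ±1 Hz, < 1 dB change beyond ±3 Hz.
2. **Resampling** to 500 Hz by polyphase filtering (`resample_poly`, i.e.
   anti-aliased).  A target rate equal to the current rate is the identity,
   which makes the conditioning chain idempotent; a target above the
   current rate is rejected.
3. **Detrending**: per-channel least-squares line over the whole recording.
4. **Channel exclusion**: contacts flagged in the channel table are
   dropped; the flags model manual artifact review and are an input, not
   something the package infers.
5. **Bipolar montage**: one derived channel per adjacent same-shank contact
   pair `(p, p+1)` (position 1 = deepest), trace = deeper − shallower.  An
   excluded contact breaks the chain — pairs never bridge a gap; this is
   the conservative reading where a montage convention is not recorded.
   The derived channel takes the deeper contact's anatomical label (the
   common sEEG convention; `label_from="shallower"` is available).
   Bookkeeping is verified against an exhaustive pair-enumeration oracle.

## Multitaper estimator

DPSS tapers are computed from the symmetric tridiagonal formulation
(diagonal `((N−1−2t)/2)² cos 2πW`, off-diagonal `t(N−t)/2`, `W = NW/N`),
selecting the K leading eigenvectors; concentrations are the sinc-kernel
quadratic forms `vᵀAv`.  Defaults: `T = 2 s`, step `T − overlap = 1.5 s`
("0.5 s overlap" is read literally as seconds, not as a fraction; a
fractional reading is a flag away), `NW = 3`, `K = 5`, uniform averaging
across tapers (no adaptive weighting — a deliberate non-goal).  Windows are
per-channel linearly detrended before tapering (`window_detrend="linear"`):
infra-resolution drift otherwise leaks through taper sidelobes and lifts
the broadband floor.  One-sided density scaling doubles interior bins only,
so the PSD integral over `[0, fs/2]` equals the signal variance (verified
to 5% on white noise); per-bin variance with K = 5 is ≈ 1/5 of the
single-taper variance.

Band conventions: half-open `[f_lo, f_hi)` on the 0.5 Hz grid, so adjacent
bands share no bin.  Condition PSDs average raw window power (windows
entirely inside the condition's interval; straddling windows count for
neither side) and are stored in dB.  Band contrasts are per-bin dB
differences aggregated by `mean` over bins (default) or `sum`; the mode is
recorded in every output row.  The `sum` mode exists because per-region
contrasts reported for studies of this design sometimes reach hundreds of
dB, which is only arithmetically possible if dB differences are summed over
bins; the package asserts neither reading and records which one was used.

## ROI statistics

Fine DKT labels map to 15 coarse groups (14 without striatum for the
propofol contrast) via shipped, editable TSVs; unmapped labels are dropped
with a logged count.  Channels are pooled across subjects per region.  The
CI is a percentile bootstrap of the mean (default `n_boot = 10,000`,
seeded, resampling channels with replacement; subject-level resampling is
an option).  Classification: `increase` iff `ci_lo > 0`, `decrease` iff
`ci_hi < 0`, else `no_change`.  No multiple-comparison correction is
applied — the output is effect sizes with CIs — and the output metadata
says so.  Contrast spectra per region (mean dB difference per frequency bin
with bootstrap CI) use the same engine; the default region set is the
posteromedial pair (posterior + isthmus cingulate).

## Synthetic study generator

The generator emulates the recording context the pipeline targets:

- **Background**: Gaussian noise spectrally shaped to
  `(f² + knee²)^(−β/2)` — log-log slope `−β` above the knee, flat below.
  Defaults `β = 1.5`, `knee = 1 Hz`, variance 1: within the range reported
  for bipolar intracranial recordings (bipolar derivation flattens the
  apparent exponent), and the knee reflects AC-coupled acquisition.
  Without a knee, most of the variance of a steep power law sits below the
  0.5 Hz window resolution and appears only as taper-sidelobe leakage.
- **Line noise**: 60 Hz plus harmonics, common-mode across the montage
  (one phase set per subject), hence visible in raw periodograms and
  cancelled by the bipolar montage as in real recordings.
- **Montage**: default 10 shanks × 10 contacts per subject, 10 subjects,
  epochs 300 s baseline / 840 s ketamine / 235 s propofol — the cohort's
  typical geometry and protocol.
- **Effects**: a band's content inside a condition's interval is scaled by
  `10^(ΔdB/20) − 1` in the interval's own rFFT basis.  This realizes the
  target power ratio exactly, keeps out-of-band coefficients untouched, and
  handles decreases (which an added independent process cannot).  The
  injected band is widened by the analysis half-bandwidth `W = 1.5 Hz` on
  each side so the downstream estimator, whose kernel smooths over `±W`,
  sees every nominal band bin fully scaled; the injection contract
  guarantees out-of-band invariance beyond that margin.  No onset ramp is
  applied by default: the injected component is a sum of in-band sinusoids,
  continuous within the epoch, so boundary discontinuities affect only
  condition-straddling windows, which the assignment rule already excludes
  (an optional raised-cosine ramp exists; on 300-s epochs a 2-s ramp biases
  a −15 dB effect by ≈ 0.7 dB).
- **Default effect topography** (magnitudes are generator choices; the
  underlying study reports estimator outputs, not signal-level truths):
  frontal gamma +10 dB under ketamine (no propofol injection, so the
  propofol−ketamine contrast is negative), occipital alpha −8 dB under
  ketamine and −16 dB under propofol, posteromedial 3–4 Hz +6 dB under
  ketamine and +12 dB under propofol (additive).

What the generator does **not** emulate: oscillatory spectral peaks in the
background, epileptiform discharges, non-stationarity within conditions,
volume conduction, or pharmacokinetic drug dynamics.  Passing tests
therefore validate the estimator and statistics, not robustness to those
phenomena.

## Numerical choices and degenerate inputs

- `to_decibels` floors exact zeros at −300 dB with a logged warning and
  rejects negative power.
- DPSS sign convention: symmetric tapers have positive mean, antisymmetric
  ones start on a positive lobe.
- Bootstrap cell seeds derive from the run seed and a cell counter
  (`SeedSequence`), making whole runs byte-reproducible.
- A condition with zero full windows, an empty band, an empty ROI, an
  unknown contact id and a band beyond Nyquist are all hard errors naming
  the offending entity; an effect ROI matching no contact is a warning
  ("unrealized"), not an error.
- EDF output is 16-bit with per-channel physical ranges (quantization step
  `range/65535`); the HDF5 container keeps float64 and is preferred for
  synthetic ground truth.

## Validation suite sizes

The validation studies (`ieegspectra.validation`) scale problem sizes for a
single CPU while keeping the analysis parameters fixed: effect recovery
uses one subject at 2000 Hz with 300-s epochs; Type-I control uses 300
null studies of 200 contacts at 256 Hz with 20-s conditions; topography
uses 20 studies of 2 subjects × 96 contacts at 512 Hz with 60-s conditions;
bootstrap coverage uses 500 Monte-Carlo replicates of 100 standard-normal
values.  Two-contact shanks are used where Type-I behavior is measured so
that bipolar channels are statistically independent — on longer shanks
adjacent derivations share a contact and their band contrasts correlate at
ρ ≈ 0.25, which narrows channel-bootstrap CIs below nominal (a property of
channel resampling on overlapping derivations, worth keeping in mind when
interpreting real-data CIs).

## Known limitations

- **Leakage floor.**  With `β = 1.5` background, taper-sidelobe leakage
  from out-of-band 1/f power sets a contrast floor near −21 dB (alpha) /
  −18 dB (3–4 Hz) relative to baseline band power: a −15 dB injected
  effect is recovered at ≈ −14.2 dB, and effects much deeper than −20 dB
  are not measurable by this estimator on such backgrounds.
- **Leakage shadows of strong effects.**  A ×16 power injection at 1.5–5.5
  Hz leaks of order 0.1 dB into other bands; with tens of pooled channels
  the bootstrap resolves this, so bands adjacent to strong low-frequency
  effects should not be expected to read `no_change`.
- **Percentile bootstrap at small n.**  With fewer than ~20 channels per
  region the percentile CI undercovers (e.g. ≈ 88% at n = 6); per-region
  channel counts are reported in every summary row so readers can judge.
- The estimator's kernel (±1.5 Hz) lower-bounds the spectral scale of
  recoverable structure: a 1-Hz-wide band is at the resolution limit and
  only measurable because injected effects are widened by the margin above.
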