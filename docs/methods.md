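# Methods

## Analysis model

The pipeline detects stimulus-locked rhythmic activity at the tagged
linguistic rates (syllable 4 Hz, phrase 2 Hz, sentence 1 Hz) in
multi-contact sEEG. Two detection paths share one spectral core:

**Broadband path.** Per contact and condition: epoch −0.5–10 s around
each stimulus onset → subtract the per-trial mean of the −0.5–0 s
baseline → drop the first post-onset second (auditory onset transient)
→ FFT of the remaining 9-s segment with a rectangular window and no
zero-padding → inter-trial phase coherence per bin → Rayleigh Z
(Z = n·ITPC²) → restrict to 0.5–4.5 Hz.

**High-gamma envelope path.** The *continuous* recording is band-passed
at 60–100 Hz (4th-order Butterworth, forward–backward, i.e. zero-phase
and effectively 8th order), the Hilbert amplitude envelope is taken,
and the envelope then goes through the identical epoch → baseline →
trim → FFT → ITPC → Z chain, with each 9-s envelope segment demeaned so
the DC bin does not dominate. Filtering and Hilbert transformation are
applied before epoching so that filter edge artifacts fall outside
trial windows. Zero-phase filtering is essential: ITPC is a pure phase
statistic, and any filter phase distortion would bias it. The upper
band edge of 100 Hz reflects the online anti-aliasing constraint of
typical clinical amplifiers; the band is configurable.

Assumptions: trials within a condition are exchangeable realizations of
the same stimulus-locked process; 9 s × the tag frequency is an integer
for every tag, so tagged energy falls on a single bin (a taper would
deliberately be wrong here — it would smear energy off the exact-bin
grid, which is why the FFT uses a rectangular window).

## Statistics and thresholding

ITPC(f) = |(1/n) Σ_r exp(iφ_r(f))| ∈ [0, 1]. Bins at which any trial
has an exactly-zero Fourier coefficient have undefined phase; they
propagate as missing (NaN) rather than being silently set to zero,
which would bias ITPC downward. Z = n·ITPC² is the Rayleigh test
statistic; under uniform phases E[Z] = 1 and Z is asymptotically
Exp(1). One-sided p-values use the standard finite-n series correction
p ≈ e^(−z)[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)].

Three threshold modes are provided:

* **literal** (default): z = 5.29, the reference analysis's published
  criterion, kept verbatim for comparability.
* **derived-normal**: the two-tailed standard-normal quantile at
  α / n_tests (n_tests = contacts × 3 conditions). This reproduces the
  published recipe's wording (and yields 1.96 at α = 0.05, one test),
  but treats Z as standard normal, which it is not.
* **derived-rayleigh**: inverts the Rayleigh p-value above. Because the
  null of Z is (corrected) exponential, this is the only mode with
  nominal false-positive calibration, and it is what the calibration
  checks use. Note the literal 5.29 is not exactly recoverable from
  either derived recipe at the published α and test count; the package
  therefore keeps the literal value as default and documents both
  derivations rather than guessing the original arithmetic.

A cell is significant when Z ≥ threshold; exact ties count as
significant. Flags are computed on the full 3 conditions × 3 tags × 2
spectrum-kinds grid. Selectivity classes use each structure's home
condition (4 Hz in syllable, 2 Hz in phrase, 1 Hz in sentence):
selective_higher_order (f_phr+ or f_sen+, f_syl−), non_selective
(higher-order positive and f_syl+), syllable_only, non_responsive.
These four classes are mutually exclusive and exhaustive. Study-wide
responding percentages are reported to 2 decimals; the per-ROI table
rounds to integers and always carries its denominators.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 20
subjects with 46–125 contacts each (1743 total), 3 conditions × 40
trials of 10-s stimulation from 250-ms syllables, 1–2 s silent
inter-trial intervals, 512 Hz sampling with one 2048 Hz subject.
Smaller designs are configured freely; validation runs use scaled-down
studies (sizes below).

Each contact is generated as the sum of:

* **1/f background noise** — white Gaussian noise shaped to power
  ∝ f^(−1) (exponent configurable), unit SD. This is the amplitude
  reference for all other components.
* **Phase-locked sinusoids** at the contact's ground-truth tagged
  rates, active only during the 10-s stimulus. The phase per (contact,
  condition, tag) is drawn once from the contact's seeded stream and
  held across trials; an optional von Mises concentration κ jitters it
  per trial to grade locking continuously. Amplitude =
  `locking_strength` × noise SD.
* **High-gamma carrier** — 60–100 Hz band-limited Gaussian noise
  (SD = `hg_scale` × noise SD), running continuously. For contacts with
  envelope-modulated tags its amplitude is multiplied by
  1 + Σ_f m·sin(2πft + φ_f) during the stimulus (depth m =
  `hg_depth`). A noise carrier rather than a tone is deliberate: it
  leaves no tag energy in the low-frequency spectrum, so envelope
  tracking and broadband tracking are dissociable by construction.

All contacts of a subject share one presentation schedule per
condition (they hear the same stimuli); per-contact seeds are spawned
deterministically from the master seed, so a (config, seed) pair
reproduces every output byte.

Ground-truth response profiles are drawn from a coarse per-ROI
probability map shaped after the reported fronto-temporal topography
(HG almost always syllable-locked, STG tracking all levels, IFG biased
toward phrase/sentence rates, sparse envelope modulation concentrated
in auditory regions). This is an *emulation* for testing detection and
classification — not a quantitative model of any real dataset, whose
per-ROI effect sizes are unknown.

Parameter defaults (units of background-noise SD unless noted):
`locking_strength` 0.2, `hg_scale` 0.5, `hg_depth` 0.4 (dimensionless
modulation depth), noise exponent 1.0. The locking strength was fixed
once from a pilot power simulation as "moderate": comfortably above
the detection threshold at 40 trials (so recovery tests exercise
classification, not luck) while keeping single-trial SNR realistic in
the sense that tagged peaks emerge only through cross-trial phase
averaging, not in single trials. Detection at the default is
deliberately not marginal; grading detection difficulty is done through
the strength parameter or κ, not the default.

What the generator does **not** emulate: epileptic and movement
artifacts, line noise, reference effects, channel cross-correlation,
non-sinusoidal or harmonically structured responses, latency
differences between regions, and attention fluctuations. Passing tests
therefore demonstrate correctness of the measurement chain on its
stated model, not robustness to every property of clinical data.

## I/O

Signals travel as 16-bit EDF. The writer fixes the physical range at
±100 µV (quantization step ≈ 0.003 µV, ~3×10⁻³ of the unit-SD
signals) and a constant start date so identical inputs give
byte-identical files; the final partial 1-s record is zero-padded.
Reading uses MNE's EDF reader, which doubles as an independent check of
the writer (round-trip error is bounded by half a quantization step,
asserted in tests). Metadata follow BIDS-iEEG-style naming
(`*_channels.tsv`, `*_electrodes.tsv`, `*_events.tsv`) without claiming
full BIDS validity. ROI labels outside the documented vocabulary {HG,
STG, MTG, ITG, IFG} map to "other" with a warning; structural problems
(duplicate ids, bad hemispheres, malformed coordinates, non-monotone
onsets) are errors.

## Numerical choices

* Frequency axes are kept exact (k/segment-length); rounding to 2
  decimals (0.11 Hz) happens only in output tables.
* Tag lookup takes the nearest bin and errors if the offset exceeds
  half a bin spacing; for 9-s segments the 1/2/4 Hz match is exact.
* Noise synthesis and the Hilbert transform run at the next fast FFT
  length and truncate/crop, purely for speed; the analysis FFT itself
  is never padded.
* Heterogeneous sampling rates are analyzed at native rate — ITPC
  depends only on phase at the tagged bins, so no resampling is needed.
* Epochs whose window does not fit the recording are dropped with a
  logged reason; an analysis aborts if more than 10% of contacts fail.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use scaled-down studies
chosen to make Monte-Carlo error small relative to the margins being
asserted: 1000 null contacts × 40 trials for false-positive
calibration (binomial 95% CI half-width ≈ 1.4 percentage points at
α = 0.05), 100 ground-truth contacts × 3 conditions for selectivity
recovery (≥95% criterion), 50 contacts per class for the
envelope/broadband dissociation, 50 replicates per strength level for
monotonicity, and a 1-subject study for byte-determinism.

## Known limitations

* The high-gamma path fixes one band (60–100 Hz); multi-band analyses
  are out of scope.
* No harmonic correction: a 2 Hz response in the sentence condition is
  reported at face value, though it could reflect a 1 Hz harmonic.
* The statistics stop at thresholding and tabulation; mixed-effects
  modelling across subjects/contacts is left to downstream tools (the
  long-format TSVs are designed as their input).
* Power-based tracking measures and time-resolved (sliding-window)
  coherence are intentionally absent; the pipeline is ITPC-only.
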