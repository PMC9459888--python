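# Methods

## Problem and pipeline

Red palm weevil (*Rhynchophorus ferrugineus*) larvae feed inside palm
trunks and are acoustically detectable long before any visual symptom.  A
distributed acoustic sensor (DAS) built on a phase-sensitive optical
time-domain reflectometer (Φ-OTDR) turns a single fiber, wound in a ~5-m
loop around each trunk, into a per-tree acoustic sensor array.  `palmdas`
implements the full detection chain and, because field recordings of this
kind are not publicly available, a physics-based simulator that generates
statistically realistic, perfectly labeled data for it:

1. **fiber model** — coherent Rayleigh backscatter with frozen random
   scatterers; acoustic sources perturb the optical phase only at their
   tree's distance bins;
2. **DSP** — normalized differential against a reference trace, zero-phase
   [100–800 Hz] band-pass, one-sided spectra;
3. **dataset** — 10×500 temporal and 10×250 spectral images per
   (tree, 100-ms window), labeled by tree condition plus a 2-dB SNR rule;
4. **CNNs** — one small convolutional classifier per image kind;
5. **decision** — strict-AND fusion of the two classifiers, FalseAlarm
   = FP/(TP+FP), and per-tree alarm counting against a threshold taken from
   reference healthy trees.

## Φ-OTDR forward model

Each distance bin (0.5 m) holds `M = 20` scatterers with Rayleigh
amplitudes `a_m`, uniform phases `φ_m`, and uniform fractional positions
`w_m` inside the ~5-m gauge set by the 50-ns pulse.  The detected intensity
is the squared coherent sum

    I_z(t) = | Σ_m a_m · exp(i(φ_m + θ_z(t)·w_m)) |²,

a direct-detection (single-photodetector) model: no phase demodulation, no
polarization, loss, or amplifier noise dynamics.  `θ_z(t)` is the acoustic
phase perturbation; acoustic-to-phase coupling is linear with a unit scale
factor (no transduction calibration exists to pin it).  A configurable
Fresnel factor (default 50×) brightens the first gauge of bins to mimic the
front-facet reflection.

Because `θ` stays small (≲0.1 rad) in every scenario modeled, the default
evaluation expands the sum to second order in `θ` using precomputed complex
moments per bin (`E0, B = Σ a w e^{iφ}, C = Σ a w² e^{iφ}`); the explicit
scatterer sum is retained as `method="exact"` and the two agree to ~1% of
the median trace intensity at these amplitudes (tested).  The expansion
makes a 5-s, 2,000-bin, 5-kHz synthesis take seconds on one core.

**Sources.** Larvae chewing is a train of Hann-windowed band-limited noise
bursts: Poisson onsets at `burst_rate = 6 /s` during the active half of a
(2 s active, 2 s silent) duty cycle, `burst_duration = 25 ms`, band
[100, 800] Hz, amplitude 0.05 rad RMS.  No published burst statistics exist
for early-instar larvae at the fiber; these defaults were chosen once as
plausible for intermittent feeding and are *not* biologically calibrated.
Their only load-bearing properties are intermittency (so infested trees
also emit quiet windows) and in-band energy ≥ 90 %.

**Wind** is a fiber-wide colored-noise phase track: flat below a 100-Hz
corner, power roll-off 40 dB/decade above it (so the [100–800 Hz] filter
leaves residual leakage that grows with speed), total power ∝ speed³
(a modeling choice; only monotonic growth is asserted), and a slow
log-normal gust envelope.  Tree loops couple 3× more strongly than loose
cable — the wound fiber rides the swaying trunk — which is what makes
healthy trees read "noisy" in wind.  **Instrument noise** is additive
intensity noise: a white floor (1 % of median trace intensity) plus a
band-limited component above 800 Hz (0.8 %), the two terms the band-pass
filter is designed around.

## DSP and labeling choices

* Differential: `d_i(z) = (I_i(z) − I_ref(z)) / I_ref(z)` with the first
  100-ms window's mean trace as reference; bins whose reference falls below
  `1e-6 ×` the median are flagged invalid and excluded from images.
* Band-pass: 4th-order Butterworth run forward-backward (`sosfiltfilt`), so
  the 10 image rows stay mutually aligned in time.  Contract (tested):
  ≥ 20 dB at ≤ 50 Hz and ≥ 1600 Hz, ≤ 1 dB ripple at 400 Hz.
* Spectra: DC dropped so 500 samples give exactly 250 one-sided components
  at 10-Hz spacing (Nyquist bin kept).
* SNR label: computed post-filter on the same 100-ms window; signal = the
  tree's loop rows, reference = a seeded 64-bin subsample of non-tree bins.
  In the intensity-differential domain additive noise is amplified by
  `1/I_ref(z)`, so cross-bin comparisons are weighted by
  `(I_ref/median I_ref)²` — an exact noise equalization — and medians are
  used on both sides; without this, trees sitting on faded speckle would be
  permanently mislabeled "noisy".  An SNR of exactly 2 dB goes to the
  not-greater side.  Infested-tree windows at ≤ 2 dB are discarded, not
  recorded (the reading of the recording rule adopted here).

## Synthetic dataset — what it emulates and what it does not

The generator reproduces the study design: equal infested/healthy example
counts with healthy split evenly into calm (controlled environment, SNR
< 2 dB) and noisy (outdoor wind 4–10 mph plus intermittent low-frequency
rustling disturbances, SNR > 2 dB).  Every scene chunk draws a **fresh
fiber realization** and jittered source amplitudes; without this, the CNNs
memorize the per-tree speckle "row fingerprint" of a handful of loops and
fail on unseen trees — the synthetic analogue of why the field study
validated on trees never used in training.  Images are normalized by their
own peak (temporal: peak |value|; spectral: peak magnitude), and each
spectral image is the row-wise spectrum of its temporal twin (recomputable,
tested).

Not emulated: bird/human/vehicle transients, rain, temperature drift of the
interferometric speckle, laser phase noise, multi-larvae choruses, and real
larvae acoustics (only a band-limited intermittent surrogate).  Passing
tests therefore demonstrate that the *pipeline* separates its classes under
the stated noise model — not field-grade accuracy on real recordings.

## CNN classifiers

Topology per branch: conv → 2×2 max-pool → conv(32 @ 3×3) → 2×2 max-pool →
flatten → dense(50, ReLU) → dense(1, sigmoid); the temporal branch's first
conv is 16 filters @ 3×50, the spectral branch's 32 @ 3×5, all stride 1×1,
valid (no-padding) convolutions — the default reading of bare kernel/stride
listings, pinned by a shape-conformance test.  Training specifics are not
published for the original models; here: Adam (lr 1e-3), batch 64, binary
cross-entropy on logits, ≤ 8 epochs with early stopping on validation loss
(patience 3), best-validation-accuracy checkpoint kept, decision threshold
0.5.  The engine is a compact seeded NumPy implementation (im2col/GEMM
convolution, float32); seeded runs are bit-reproducible on one machine.

## Decision stage

A window is "infested" iff **both** branches say so (logical AND), which can
only shrink FP and TP relative to either branch (exact bound, tested); the
empirical consequence FalseAlarm_merged ≤ min(branch FalseAlarms) is checked
stochastically on the synthetic evaluation set — it is not analytically
guaranteed.  The alarm unit is one 100-ms image pair per tree.  Tree-level
verdicts use threshold = max alarm count among reference healthy trees
(safety factor 1.0); a tree is announced infested iff its count is
*strictly* greater.  Because an infested tree also emits healthy windows,
ledgers report raw counts and normalized rates.

## Problem sizes and seeds

Default evaluation scale, chosen as the package's study condition: 4,000
image pairs per branch (2,000 infested / 1,000 calm / 1,000 noisy),
60/20/20 stratified split; alarm experiments run 30 s (300 windows/tree) on
a 400-m, four-tree farm (two infested, two healthy) at 0, 4, 8 and 12 mph.
One global seed fans out per stage via `SeedSequence((seed, stage_index))`.

## Known limitations

* The small-signal expansion saturates fidelity near ~0.3 rad phase
  amplitude; very loud sources need `method="exact"`.
* Wind-speed mapping (power ∝ speed³, 3× tree coupling) is uncalibrated;
  conclusions about absolute wind thresholds (e.g. "degrades above 9 mph")
  transfer only qualitatively.
* The calm class is near-degenerate (pure receiver noise), making the
  signal-level task easier than field data; accuracy numbers on synthetic
  data are upper bounds in that respect, which is why tree-level
  experiments with unseen fiber realizations are the stronger check.
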