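# Methods

This note documents the models, numerical choices and limitations behind
`pelvimag`. It is written for someone who wants to judge what the package's
tests do — and do not — demonstrate about real pelvic-floor MMG data.

## Signal model of the synthetic generator

The generator emulates one recording session of the study protocol: a
participant over a 151-sensor curved SQUID array performs graded Kegels
(small/moderate/strong), then isolated abdominal and thigh contractions,
each 10 s with 10 s rest, at 1200 Hz. Onsets therefore fall exactly on a
`rest + k·(contraction + rest)` grid, which the epoching stage relies on
only through the recorded annotations.

**Sensor layout.** MMG sensors sit on a sunflower (Fibonacci) grid over a
spherical cap (radius 0.13 m, half-angle 60°). The lowest-lying sensors
(default 20) form the analysis subset (`mmg_lower`, closest to the pelvic
floor); thigh-interference references (default 12) are the most lateral
sensors of the outer ring, excluding the bottom sector. This exclusion
matters: reference channels must see as little of the pelvic source as
possible, because the SUBTR regression will cancel from the targets
anything coherent with its references. Six bipolar surface-EMG channels
(perineum, abdomen, thigh) and one ECG channel are appended.

**Contraction bursts.** Each burst is Gaussian noise split into the three
analysis bands (20–80 / 80–140 / 140–200 Hz) by brick-wall masking of its
rFFT. The components are exactly orthogonal (disjoint spectral support) and
unit-RMS, so mixing them with √w weights realizes the requested band-power
fractions *by construction* — the generator's band ground truth is analytic,
not estimated. Bursts are enveloped with 0.5 s raised-cosine ramps (the
protocol does not specify contraction dynamics; the ramp avoids spectral
splatter) and projected onto the array with exponential spatial falloff
(decay length 0.045 m) from a role-specific source point, truncated to zero
beyond 0.12 m. The compact support keeps the distant reference sensors
genuinely signal-free; without it, a low-rank simulation (one waveform times
a gain vector) lets the multichannel regression reconstruct the burst from
an arbitrarily small leak, which no physical reference montage would permit.

**Interference.** Thigh activity is modelled as one source per side at the
lateral reference groups (strongest on edge sensors and thigh EMG);
abdominal activity projects weakly onto the upper array and abdominal EMG;
the cardiac artifact is a three-Gaussian QRS-like template repeated at
70 bpm with ±5 % beat jitter, present on every channel with per-sensor gain
variation and ×10 on the ECG channel; a 60 Hz tone and white sensor noise
are added everywhere. Default levels (40 / 20 / 15 / 10 / 5 fT RMS) were
chosen once so that a raw moderate Kegel sits only ~2 dB above baseline and
becomes clearly detectable (~10 dB) after cleaning — i.e. the QC gate does
real work.

**Amplitudes and effects.** Default burst amplitudes are 30 / 60 / 120 fT
for small/moderate/strong Kegels, placed relative to the ~120 fT moderate-
Kegel RMS reported for never-pregnant women in earlier MMG work, with
pregnant values lower. The paired-study effect defaults — postpartum
amplitude ratio 0.8, band-weight shifts −0.10 (low) and +0.10 (middle),
between-subject SDs 0.15 (log-amplitude) and 0.05 (weights) — reproduce the
directions reported in the pregnancy/postpartum comparison and are the
conditions under which the statistical stage is calibrated. Subject
parameters derive from `seed + subject_index`, so studies are reproducible
per subject.

**What the generator does not model:** volume conduction or any
magnetostatic forward model, fetal signals, sensor drift, movement
artifacts, or within-burst amplitude variability beyond the envelope.
Passing tests show the *pipeline* recovers what the generator injects; they
do not validate the generator against real physiology.

## Preprocessing

**SUBTR.** Per STFT bin (Hann window, 1 s, 50 % hop — perfect-reconstruction
overlap-add via the canonical dual window), the complex weights solve the
least-squares regression of target-channel coefficients on reference
coefficients: W(f) = S_yx(f)[S_xx(f) + λI]⁻¹ with diagonal loading
λ = 10⁻³ × mean reference power per bin (silent bins are skipped).
Estimation variance per bin scales as 1/n_frames, which sets the tolerance
of the oracle-equivalence test against direct time-domain least squares.

**Filters.** 4th-order Butterworth band-pass (20–200 Hz) as second-order
sections plus a 2nd-order IIR notch (60 Hz, Q = 30), both applied
forward–backward. Zero-phase application squares each magnitude response —
the designed 100 Hz gain is 0.999 and the notch floor is far below the
30 dB contract — and keeps trigger-locked amplitude features free of phase
distortion.

**ICA.** FastICA (negentropy fixed point) on the MMG channels, at most 40
components, seeded. Rejection policy (ours; thresholds configurable):
|Pearson r| > 0.8 with the ECG trace, or > 80 % of mixing-column energy on
edge-reference sensors. Two numerical realities shape the implementation:
(i) the unmixing can be fitted on decimated samples and applied to the full
record — reconstruction is exact whenever the decomposition is full rank,
since mixing = pinv(unmixing); (ii) the fixed-point convergence criterion
cannot settle when part of the whitened space is near-Gaussian (rotations
within a Gaussian subspace are unidentifiable), even though strongly
non-Gaussian components such as the QRS train are isolated within the first
iterations. The operation therefore retries with fresh seeds and fails
explicitly by default, while the orchestrated pipeline opts into a
warn-and-keep policy (one attempt, 200 iterations, 4× decimation) and
records convergence in the QC report.

**Stage order** is SUBTR → band-pass/notch → ICA for MMG; EMG channels
additionally get ECG-referenced SUBTR. Cardiac residue on MMG channels is
handled by the ICA ECG-correlation rule.

## Epoching, QC, features

Epochs span −3 s…+10 s around each onset (sample indices by rounding
onset × fs; 15 600 samples at 1200 Hz); the trigger sample belongs to the
signal interval. Out-of-bounds windows are dropped with a warning rather
than zero-padded, which would bias baseline statistics. Baseline correction
subtracts the per-channel mean of the 3 s pre-trigger interval.

SNR pools RMS over the lower-sensor subset (a best-single-channel variant
is available); the gate discards epochs strictly below 1 dB — a value at
exactly the threshold is kept, with a 10⁻⁹ dB tolerance absorbing float
round-off in the log ratio. A (subject, session) cell with no surviving
epochs excludes that subject from the paired analysis entirely.

The sliding-RMS window is 240 samples with a 1-sample hop: the nominal
200 ms / 199 ms parameters imply a 1.2-sample hop at 1200 Hz, and a
1-sample hop is the closest realizable without fractional resampling
(slightly denser than nominal). The per-epoch scalar RMS is the *mean* of
the smoothed series over the contraction interval (configurable to max),
averaged over lower sensors. Total power is the *sum* of Welch density bins
in 20–200 Hz inclusive (not × Δf), matching how such totals are reported in
this literature; at the 1 s window the grid is 1 Hz, so the flat-spectrum
band counts are 60/60/61. Band-edge bins are assigned half-open —
[20, 80), [80, 140), [140, 200] — so every bin counts exactly once and the
three fractions sum to 1 to machine precision.

## Statistics

Per-subject grand averages over kept moderate-Kegel epochs give one paired
sample per parameter. The comparison is a two-sided paired Student t-test
on differences d = pregnancy − postpartum (t = d̄/(s_d/√n), df = n−1),
preceded by a Shapiro–Wilk check on d. The normality check never gates the
t-test: when it fails (p < 0.05) the result carries a warning and a
supplementary Wilcoxon signed-rank p-value. No multiple-testing correction
is applied across the five parameters, matching the per-parameter α = 0.05
convention of the source analyses. Degenerate cases (zero difference
variance) are flagged explicitly rather than reported as t = 0.

Monte-Carlo calibration (type-I rate within the binomial band at 1000
replicate null studies; ≥ 80 % detection of the ±0.10 band shifts at n = 9)
runs on a parameter-level study sampler that draws per-epoch features
directly from the subject-parameter model with 5 % relative epoch noise.
Synthesizing waveforms for thousands of replicate studies would add hours
of compute without changing what the calibration measures — the behaviour
of the averaging and testing stages. The waveform path is exercised
end-to-end separately.

## Problem sizes

Tests and the acceptance script run the waveform pipeline at reduced scale
— 16–32 MMG sensors, 1–2 Kegel cycles, 2–9 subjects — while keeping the
protocol timing, sampling rate, signal model and all analysis parameters at
their study values. Sensor count and repetition count enter the analysis
only through averaging, so the reductions change variance, not behaviour.
The default `SessionSpec` remains the full 151-sensor, 3-cycle protocol.

## Known limitations

- The SUBTR estimator is stationary per session; time-varying coupling
  (posture shifts) is not tracked.
- ICA component count and rejection thresholds are policy, not estimated
  from data; on heavily Gaussian data the decomposition is reproducible but
  formally unconverged (reported as such).
- The rPSD is compositional; the per-band t-tests ignore the sum-to-one
  constraint, as is conventional.
- Power maps use sensor positions only (no interpolation to a head/torso
  surface); rendering is a minimal scatter overlay.
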