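# Methods

## Generative model of the synthetic cohort

Each simulated participant's recording is a sum of four components on a
fixed montage (F3 Fz F4 / C3 Cz C4 / P3 Pz P4 / O1 Oz O2 plus mastoids
M1 M2) at 500 Hz, in microvolts:

* **Background activity** — Gaussian noise with a 1/f^a power spectrum
  (`noise_exponent`, default a = 1; `noise_sd` = 20 µV per scalp
  channel; mastoids carry 40% of that). Generated by spectral shaping of
  white noise, DC removed.
* **Spontaneous slow oscillations** — a renewal process (one cycle plus
  an exponential gap) with event rate `spont_so_rate` = 0.55/s. Each
  event is a negative then positive half-sine of total duration
  1/`so_freq` (0.75 Hz → 1.33 s), jittered by 8%, with peak-to-peak
  amplitude ~N(150, 45) µV at Fz and a fronto-central spatial profile
  (Fz heaviest).
* **Word-evoked response** — on each trial, with probability
  `entrain_prob` = 0.32, a fixed-latency sequence of half-sine lobes: a
  down-state at 500 ms (width 350 ms, gain 0.5), up-states at 1000 and
  2400 ms (widths 700/650 ms), and a weak intermediate down-state at
  1750 ms representing the trough of the entrained ~0.7 Hz sequence.
  Up-state lobes have a centro-parietal profile (P4 heaviest), down
  lobes a central one (C4 heaviest). The participant-level lobe
  amplitude A_p ~ N(62, 18) µV is the ground truth for the
  brain–behaviour coupling; trials additionally scale by
  max(0, N(1, 0.35)). Lobes are fixed-latency additions, not phase
  resets: downstream analyses consume only event-locked averages and
  discrete SO peaks, for which the two mechanisms are indistinguishable.
* **Spindles** — Hanning-windowed sinusoidal bursts (0.8 s, 5 µV): a
  slow spindle (11 Hz, frontal weighting) centred on the down-state and
  a fast spindle (15 Hz, centro-parietal) centred on up-state 1, only on
  entrained trials.

The stimulation schedule presents `n_words` = 56 nouns, half once and
half six times (196 presentations), strictly every `isi` = 4 s, shuffled
with no immediate repetition. Artifacts, when requested, are Poisson
intervals (1–3 s) whose samples are replaced by 300 µV noise.

**Behaviour.** The expected semantic priming score of participant p is
`coupling_beta · z(A_p)` dB(A) where z standardises A_p by the
configured cohort mean/SD; the expected perceptual priming score is the
same quantity times `perceptual_scale` = 150 ms/dB. A single dial,
`noise_sd_behavior` (default 0.5 dB), sets the participant-level score
noise and, scaled (×4 dB for volumes, ×400 ms for RTs), the
word/trial-level noise — so a noise-free configuration encodes the
coupling exactly and rank correlations reach 1. Identification volumes
are continuous dB(A) values clipped at the 38.7 dB(A) staircase start
(not quantised to the 2.5 dB step: quantisation would put a floor on
behavioural noise and break the exact noise-free limit). 2AFC
correctness is Bernoulli(0.5) — forced guessing — and RTs are N(2750,
·) ms with the incorrect-choice mean shifted by the perceptual score.

**Calibration.** `spont_so_rate`, the SO amplitude distribution,
`entrain_prob`, A_p's moments and `coupling_beta` were calibrated once
so that the default cohort reproduces the empirical regime the package
targets: detected up-state rates of ≈0.45/0.46 per s inside the evoked
up-state windows versus ≈0.34 per s in the down-state window, and
typical up-state-amplitude/priming rank correlations of ≈0.5–0.65 at
n = 16. They are study conditions, not free dials.

**What the generator does not emulate** — sleep-stage dynamics,
arousals as physiological processes, word acoustics/semantics,
spatially correlated noise, electrode drift, or K-complexes. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated statistical structure, not performance on real polysomnography.

## Analysis conventions and numerical choices

* **Epochs** are half-open [−1000, +3000) ms; at 500 Hz an epoch has
  exactly 2000 samples, and baseline correction subtracts the mean of
  all samples with t < 0. ERPs are computed on unfiltered data.
* **Trial exclusion**: an event is excluded when its onset lies within
  3 s before the start of a rejected interval *or inside it* (the
  conservative reading of overlap), with cascade to all presentations of
  the same word. Flags are monotone and idempotent.
* **SO detection** runs on Fz (configurable). The filter chain is
  zero-phase (forward–backward Butterworth: 30 Hz low-pass order 4,
  0.15–2 Hz band-pass order 3) so peak times are comparable with ERP
  latencies; its gain at 1 Hz is within 5% of unity. Down-sampling to
  250 Hz uses decimation for integer ratios, polyphase resampling
  otherwise. The 2/3 amplitude thresholds are computed over the
  duration-passing candidate pool of the same recording — both criteria
  are relative, making the accepted set scale-invariant. Peristimulus
  bins are left-closed ([edge, edge+0.2)); a peak exactly on an edge
  counts rightward. z-scores use the population SD, with zero-variance
  inputs mapped to zero.
* **ERSP kernels** are Gaussian-windowed complex sinusoids of total
  length c(f)/f seconds, c(f) linear from 3 cycles at 4 Hz to 20.0625
  at 53.5 Hz, Gaussian σ = length/6, unit L2 norm. The fixed output
  grid (100 × 200, −582…2582 ms) is the largest for which every kernel
  fits inside the epoch; the ~834 ms window at the lowest frequency
  governs that valid range. Stage-1 normalisation divides by the mean
  power over the 200 output times of the same epoch and frequency;
  stage 2 subtracts the per-frequency pre-stimulus (t < 0) mean. The
  alpha band is deliberately 4–12 Hz, overlapping theta, and gamma is
  the half-open (24, 50] Hz, mirroring the conventions of the analyses
  this package reproduces.
* **Cluster statistics**: two-tailed pointwise threshold from the t
  distribution (df = n−1); adjacency is ±1 time sample, ±1 frequency
  bin, and rook neighbours on the 4×3 electrode grid (no diagonals,
  configurable); opposite signs never merge. The null permutes by
  per-participant sign flips — the operational meaning of exchanging
  evoked signal and baseline for baseline-subtracted maps — and each
  permutation re-uses the identical t-map code path so that a
  permutation reproducing the observed signs yields a bit-identical
  mass (ties count as "same or larger"). The observed statistic is not
  added to the null; p = 0 is reported with a ceiling of 1/n_perm.
  Zero-variance points get t = 0 (zero mean) or a ±1e6 sentinel.
* **Topographies** are z-scored across electrodes per participant
  (population SD). The spontaneous topographies are read from the
  SO-triggered average at −196 ms (down) and +176 ms (up) around the
  down-to-up transition; entrained topographies are each participant's
  ERP at the *group* cluster peak time (per-participant peak picking
  would inflate amplitudes through selection bias). The Topography ×
  Event contrast is a two-way repeated-measures ANOVA (pingouin);
  partial η² = SS_int/(SS_int + SS_err) is recovered from the reported
  SS, F and dfs. No sphericity correction is applied — a documented
  limitation, acceptable because only the interaction's existence is
  interpreted.
* **Effect size** r = sign(t)·√(t²/(t²+df)) carries the sign of t; the
  sign convention is this package's own (conventions differ in the
  field) and is stated wherever r is reported. Correlations are
  Spearman (average ranks for ties), two-tailed, uncorrected — with 12+
  correlations at n = 16 these are descriptive, not confirmatory.
* **Once- vs six-fold conditions** are pooled for all statistics;
  condition labels are retained in the tables for stratified reporting.

## Pipeline and problem sizes

`run_pipeline` processes participants sequentially (one recording in
memory at a time), then runs the group ERP cluster test (default 1000
permutations), identifies the down-state/up-state-1/up-state-2 clusters
by sign and peak-time proximity to the configured latencies, computes
per-participant cluster-mean amplitudes, up-state rates inside the
cluster windows, z-scored bin series, topography ANOVAs, band-power
contrasts on an epoch/channel subset (default 30 epochs, Fz), priming
scores and the correlation table, and writes a manifest with SHA-256
hashes of every output. Identical config + seed ⇒ identical hashes.

The acceptance script uses the full default cohort (16 participants ×
196 presentations, 600 permutations) and scales the property
simulations to 200 null cohorts × 200 permutations on a 10 × 6 map and
a 2⁶ exhaustive enumeration — sizes chosen so the whole script
completes in about a minute on one CPU while keeping Monte-Carlo error
well below the tolerances of interest.

## Known limitations

* The ERP's across-participant variability is dominated by a common
  gain (A_p), so pointwise t-values are nearly flat across electrodes;
  peak-electrode labels in the cluster report are less stable than peak
  times. Topography contrasts use the z-scored maps and are unaffected.
* The down-state magnitude is (negatively) coupled to A_p by
  construction, so the synthetic cohort shows a negative
  down-state/priming correlation that real data need not show.
* EDF export is not implemented (no EDF-writing backend is declared);
  recordings serialise to HDF5, and EDF *reading* is available via MNE.
* With very short recordings or high artifact rates the pipeline can
  fail to identify all three responses; it then reports the subset and
  logs a warning rather than failing.
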