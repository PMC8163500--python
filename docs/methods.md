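# Methods

This note documents the models, parameter choices and numerical decisions
behind `hftag`, and what the synthetic data can and cannot establish.

## Stimulus model

Each syllable token occupies exactly one 250 ms slot at a working audio
rate of 1000 Hz (250 samples per slot; the round rate is preferred over
hardware-specific rates so slot arithmetic is exact).  A token is a
band-limited Gaussian noise carrier (center 150–300 Hz, bandwidth 250 Hz)
shaped by an amplitude kernel: a fast-rise / strong-decay base contour
(rise 2–5% of the active part, decay to 10–30% of peak) multiplied by a
token-specific smooth random contour (±30%, low-passed at ~40 Hz).  The
kernel tail fades monotonically to zero over its last 25 ms, the de-click
treatment applied when recorded syllables are truncated to the slot.
All tokens are scaled to identical RMS over the full slot (equal loudness).

Half of each bank emulates **word-initial** syllables (energy filling the
slot) and half **word-final** syllables (a 70–90% active part followed by
silence padding, as when a shorter recording is padded out).  Structured
sentences draw word-initial tokens at even positions and word-final tokens
at odd positions from a fixed inventory (12 eight-syllable sentences by
default).  This is what produces the acoustic 2 Hz word-rate component in
the Structured envelope: the two syllable classes alternate at 2 Hz,
mirroring the real stimuli in which a consistently different subset of
syllables occurs at word-initial versus word-final positions.  No explicit
2 Hz modulation is injected, and the same token statistics in random order
(Non-Structured) produce no such component.  Within-class contour
variability is kept moderate so that the residual deterministic energy at
1 Hz and 0.5 Hz (from finite per-position token subsets) stays well below
the 2 Hz component; with the defaults the 4 Hz bin exceeds its four
flanking bins by >10x in both conditions and the 1/0.5 Hz excesses are
<20% of the 2 Hz excess.

The modulation spectrum mirrors the neural spectral analysis exactly:
RMS envelope (10 ms centred window, reflect padding to avoid onset
transients), non-overlapping 8 s segments from the sequence start (after
discarding a 3 s onset ramp when one was applied), FFT magnitude per
segment, mean across segments.  Segments are assumed non-overlapping, as
in the neural segmentation.

## Simulated recordings

Neural data are simulated at 250 Hz (Nyquist far above the 15 Hz analysis
ceiling) on a 16-channel grid standing in for a sensor array; trials are
22 sentences = 44 s long (whole sentences; inside the 44.53 ± 3.23 s band
of the narrated materials).  Per trial the simulator sums:

* **syllable response** — a fixed biphasic kernel (150 ms support)
  convolved with the 4 Hz onset train, on all channels
  (`syllable_response_amp`, default 0.4);
* **phrase response** — a 1 Hz sinusoid phase-locked to sentence onsets,
  only in Structured trials and only on `phrase_channels` (default
  channels 0, 1, 4, 5 — the "left frontal/parietal" group of the
  grid).  Its phase is fixed per participant and varies across
  participants, which is exactly the phase-consistency structure the ITPC
  statistic assumes; no biophysical parsing model is implied
  (`phrase_response_amp`, default 0.028);
* **speech tracking** — the true TRF (lobes at 80 and 140 ms, alternating
  channel polarity as for a dipolar field) convolved with the attended
  envelope; in Structured trials the kernel is scaled by 1.5 within
  70–180 ms on a channel group, the injected condition effect
  (`trf_amp`, default 0.01);
* **noise** — unit-variance 1/f Gaussian noise (`noise_exponent` 1.0).

Attended narratives are simulated as positive envelopes of 8 Hz-low-passed
noise; real narrated speech has richer temporal and spectral structure.

**Amplitude calibration.** The published group effect sizes anchor the
defaults, chosen once by a documented procedure: with unit noise,
`trf_amp` is set so scalp-level predictive power lands near r = 0.1;
`syllable_response_amp` so the 4 Hz FOI effect is large (d ≈ 2.2–2.7,
matching "d > 1.5"); `phrase_response_amp` so the between-condition 1 Hz
effect is moderate (d ≈ 0.6–1.0 across simulation seeds, against the
published d = 0.57).  Per-participant variability uses log-normal gains
(σ = 0.45 at the phrase rate, 0.2 at the syllable rate) and uniform
0.7–1.3 channel gains.

**What passing tests show.** Recovery of injected effects demonstrates
that the statistics detect exactly the structure they assume
(segment-onset phase locking, linear envelope tracking, channel-confined
effects) at realistic effect sizes and noise.  It does not show robustness
to artifacts, sensor geometry, source leakage, head-movement or any other
property of real MEG; artifact rejection and source estimation are out of
scope, and the 22-ROI anatomy is abstracted to labeled channel groups.

## Spectral statistics

ITPC uses the Rayleigh statistic z = m·R̄² computed from raw (un-tapered)
8 s segment FFTs: the tag rates fall exactly on the 0.125 Hz bin grid, and
tapering would leak phase across bins.  The analysis grid is the FFT grid
0.125–15 Hz; a nominal 0.1 Hz start is not representable on an 8 s grid
and no interpolation is attempted.  Segments are pooled over trials within
participant and condition before computing z (segments, not trials, are
the unit of phase consistency).  The scalp-level statistic averages z over
channels *before* the group test; FOI tests compare z at the tag frequency
against the mean of two bins per side, two-sided within condition, and the
between-condition permutation test is one-sided (Structured > 
Non-Structured, the predicted direction).

## Permutation schemes

"Swap the labels of half of the participants" is implemented literally: a
uniformly random subset of exactly ⌊n/2⌋ participants per permutation
(equivalently, sign flips of that subset's paired differences).  The
independent-coin-flip convention of common toolboxes is available as
`scheme="bernoulli"`.  All p-values use the add-one rule
p = (1 + #{null ≥ observed}) / (1 + n_perm), so ties count conservatively
and the smallest attainable p is 1/(n_perm + 1).

The ROI global statistic sums *signed* t over ROIs passing an uncorrected
two-sided p < 0.05 (the predicted direction is positive; an |t| variant is
exposed via `signed=False`), evaluated one-sided against the top 5% of its
half-swap null, separately per hemisphere.

The cluster test thresholds the first-level paired-t map two-sided at
p < 0.05, groups same-sign suprathreshold points connected through
adjacent time bins or adjacent channels (user-supplied adjacency; the
bundled fixture is a rook-adjacency grid; units without neighbours warn
and act as singletons), and refers each cluster's mass (sum of t) to the
permutation distribution of the maximum |mass| under per-participant sign
flips.  Cluster identification is verified against a brute-force
flood-fill oracle, and the whole test against MNE's implementation and
exhaustive sign-flip enumeration at n = 8.

The ROI-windowed TRF comparison averages kernels in consecutive 20 ms
windows tiling 70–180 ms; the trailing window that does not fully fit is
dropped (5 full windows), avoiding an unequal-variance final bin.

## TRF estimation

Normalized reverse correlation in the lag domain, default lags −50…400 ms
(covering both response lobes with margin).  Envelopes are z-scored per
trial (the feature transform is otherwise unspecified; z-scoring makes
predictive power scale-free).  The stimulus autocovariance is accumulated
over trials and pseudo-inverted after keeping the leading eigencomponents
holding a `tolerance` fraction of eigenvalue mass; `sparseness` zeroes
coefficients whose jackknife |mean|/SE falls below the threshold.  These
two operationalizations make the toolkit-style "tolerance" and
"sparseness" factors concrete and testable.  Predictive power is Pearson r
between leave-one-trial-out predictions and held-out responses, averaged
over folds and channels, discarding one lag-range of samples at each trial
edge; the mismatched-pairing null re-pairs every envelope with a
non-matching response (sampled derangements) and repeats the identical
procedure.  Hyperparameters are selected once on condition-pooled data and
reused for both conditions.  Numeric grids for tolerance/sparseness are a
package choice (default tolerance {1.0, 0.95}, sparseness {0}); with
low-passed envelopes the autocovariance is ill-conditioned and truncation
is essential — the full solve (tolerance 1) yields noise-dominated kernels
at realistic SNR even when its in-sample predictions look fine.

## Behavioral statistics

Chance is exactly 1/3 (3-alternative questions); 0.33 is display rounding.
The median split on 1 Hz Structured ITPC assigns the median participant to
the lower group when n is odd (15/14 at n = 29), and between-group tests
are two-tailed.  A zero-variance accuracy vector away from chance is
reported as a degenerate case rather than an infinite t.

## Problem sizes and determinism

The bundled presets are `tiny` (6 participants, 4 trials/condition,
16 channels, 200 permutations — a complete pipeline exercise in ~20 s) and
`default` (29 participants, 15 trials/condition, 1000 permutations — the
published cohort scale, a few minutes).  Type-I calibration uses 400 null
replicates at 100 permutations each; power checks use 50 replicates at
500 permutations.  A single master seed deterministically derives every
stage seed (a fixed hash of the stage name mixed into a seeded generator),
so reports are byte-identical across reruns; every permutation table
records the seed that produced it.

## Known limitations

* The phrase-rate injection is a pure sinusoid; real phrase tracking is
  neither sinusoidal nor strictly stationary.  Only its segment-onset
  phase consistency matters to the statistics exercised here.
* The 2 Hz acoustic confound is reproduced structurally but its size is
  not fitted to the real stimulus corpus.
* No word-rate (2 Hz) or sentence-rate (0.5 Hz) neural response is
  simulated, matching the null findings being emulated, so the pipeline's
  behaviour under a true 2 Hz neural response is untested.
* Channel adjacency, ROI parcellation and hemisphere labels are abstract
  stand-ins; nothing here validates anatomical localization.
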