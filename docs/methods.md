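# Methods

This note documents the models and procedures implemented in `songeval`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real recordings.

## Time–frequency representation and acoustic features

All audio analysis runs on a multitaper spectrogram: 10 ms analysis
windows advanced in 1 ms steps, each multiplied by the first k = 2 DPSS
tapers with time–bandwidth product 1.5, power averaged over taper
eigenspectra.  Frame timestamps are window centers; all times are
milliseconds from clip start and intervals are half-open `[onset,
offset)`.  The frame count is `floor((n_samples − window)/step) + 1`.
Feature analysis and stereotypy are restricted to 860 Hz–8.6 kHz, one
consistent band across modules; zebra finch song carries most of its
energy there and the band excludes low-frequency cage noise.

Per-frame features follow the Sound-Analysis-Pro tradition, re-specified
here explicitly because only the feature *names* are standardized:

* **amplitude** — 10·log10 of total band power (dB, arbitrary reference);
* **Wiener entropy** — log of the ratio of geometric to arithmetic mean
  of band power; ≤ 0 by Jensen's inequality, ≈ 0 for white noise,
  strongly negative for tones;
* **pitch / pitch goodness** — location and height of the peak of the
  real cepstrum (inverse FFT of log power) in the 400–6000 Hz fundamental
  range; a harmonic stack with fundamental f0 peaks at quefrency 1/f0;
* **FM** — the angle atan2(‖∂log P/∂t‖, ‖∂log P/∂f‖) in degrees over band
  bins: 0 for steady tones, rising toward 90° for fast sweeps.

**Silence convention.** Frames whose amplitude falls below the gate —
noise floor (10th percentile of frame amplitudes) + 12 dB, capped 20 dB
below the loudest frame so all-sound clips are not gated away — are
flagged; they carry amplitude = floor, entropy = 0, pitch = 0,
goodness = 0, and are excluded from feature histograms, from
similarity-diagonal means, and from stereotypy correlation
normalization.  Features are therefore never NaN.

**Syllable segmentation** is amplitude gating on the same threshold:
maximal supra-threshold runs, gaps < 5 ms merged, runs < 10 ms discarded.
The threshold and both duration parameters are config-exposed; they are
this package's defaults, not a claim about any particular prior study's
segmentation.

## Imitation scoring

Similarity between tutor frame i and pupil frame j is `exp(−d(i,j)/τ)`
with d the Euclidean distance between feature vectors (FM, Wiener
entropy, pitch goodness, pitch) z-scored by the tutor track's statistics.
Two open choices are made here and exposed in configuration:

* **τ** defaults to the median pairwise distance among the tutor's own
  frames (the tutor acting as reference corpus).  A scale estimated from
  each tutor–pupil pair would inflate the similarity of bad imitations —
  large distances would stretch τ — so the scale is fixed per tutor,
  keeping scores comparable across pupils and monotone under distortion.
* **Sectioning**: pupil bouts are cut into sections of twice the tutor
  motif duration advancing by one motif duration (50% overlap), the last
  section right-aligned; every motif-length stretch of the pupil then
  lies wholly inside some section.

Each tutor syllable is scored at every diagonal placement (section ×
offset) as the mean similarity along the aligned syllable-length
diagonal, silent pupil frames excluded; ties break to the earliest
section, then earliest offset, for determinism.  The acoustic score is
the duration-weighted mean of per-syllable best similarities (weighting
is a package choice; the aggregation was not standardized).  The sequence
score re-scores the preceding and following tutor syllables at the
positions they would occupy if the pupil preserved the tutor's local
timing around each match, averaging all defined neighbor comparisons;
single-syllable motifs score 1 by convention and are flagged.  Bout-level
aggregation is an unweighted mean over bouts, and the composite score is
exactly acoustic × sequence.

**Self-similarity** reuses the machinery with the reference bird's own
song supplying the motif — by default the leading third of the first
reference bout, cropped to syllable boundaries (the fraction keeps the
remaining bouts at least twice the motif's length).  Normalizing a
post-manipulation score by the pre/pre score gives a degradation index
equal to 1 for unchanged song.

**Imitation capacity** is the affine rescaling
`(score − 0.104)/0.093` with loss its complement; the anchors (unrelated
adult mean 0.104, control mean 0.197) are configurable.  Values outside
[0, 1] are returned unclipped with a flag: synthetic pupils can exceed
the ceiling measured on real birds.

## Stereotypy and maturity

The spectrogram similarity of two clips is the peak of their lag
correlation: Pearson correlation of band-restricted power between each
pair of 1 ms slices, summed along diagonals, normalized by the number of
overlapping valid slices at each lag (unnormalized diagonal sums trivially
favor the longest diagonal), with a minimum-overlap fraction of 0.5 of
the shorter clip's valid slices to suppress edge spikes.  Syllable
stereotypy selects 100 syllables without replacement, compares each
against 100 syllables sampled with replacement (excluding the selected
syllable itself — both choices configurable, as the original sampling
scheme is under-specified), takes the 95th percentile of each similarity
distribution (linear interpolation between closest ranks), and averages.
The maturity index is the mean pairwise peak over whole bouts.

## Neural response statistics

* **Window test**: paired t-test across events of spike counts in
  `[onset, onset+150 ms)` vs `[onset−150 ms, onset)`; all-zero
  differences return p = 1, flagged.
* **Circular-shift bootstrap**: spikes within ±1 s of each event are
  rotated by per-event shifts drawn uniformly from ±1 s, wrapping within
  the 2 s window; 1000 surrogates by default.  The PSTH peak (10 ms bins
  by default — the bin width behind the original histograms is not
  stated, and 10 ms resolves the fast responses without empty-bin noise)
  is computed within the 1 s post-stimulus window with the *identical*
  statistic for real and surrogate data, so real and surrogate peaks are
  exchangeable under the null and the 95th-percentile criterion has its
  nominal level.  The continuous exceedance fraction is returned
  alongside the binary criterion.  Because spike counts are integers the
  peak distribution has atoms and the criterion is mildly conservative:
  measured type-I error on 5 Hz Poisson units with 60 events is ≈ 0.03–
  0.045 rather than 0.05.
* **Population test**: each unit's averaged response is rotated by an
  independent uniform shift before averaging; the population peak rate
  and the maximal 150 ms spike count form two null distributions, the
  real values within 150 ms of onset are tested against them, and the
  reported p is the larger of the two exceedance probabilities.
* **Latency/duration**: 2 ms bins; each post-onset bin's pooled count is
  z-tested (normal approximation, 0.5-count continuity correction)
  against the mean and SD of the 500 pre-stimulus bin counts.  Latency is
  the left edge of the first bin opening 5 consecutive significant bins
  (two-sided p < 0.05); the response ends at the first later bin opening
  10 consecutive non-significant bins.  A zero-variance baseline raises
  an error.  The duration estimate has a small upward tail: an isolated
  baseline bin of ≥ 6 counts just after the true offset is genuinely
  significant at p < 0.05 (probability ≈ 0.017 per bin under a
  2-count-mean baseline) and postpones the quiet run; at the reference
  simulation conditions this perturbs the estimate by > 10 ms in ≈ 8% of
  runs.  This is intrinsic to the rule at α = 0.05, not an implementation
  artifact.
* **Motif-locked modulation**: motifs aligned on onset and truncated to
  the shortest duration; per-motif spikes rotated within the motif span;
  p is the surrogate-peak exceedance fraction.
* **Antidromic test**: band power is the sum of `|X_k|²/N²` over
  periodogram bins with 200 Hz ≤ k·sr/N ≤ 2 kHz (rectangular window) in
  the 2–17 ms post-stimulus window.  The averaged-trace band power is the
  site-level response summary; significance is a one-sided Welch t-test
  of *per-trial* band powers against reference (no-response) trials,
  which yields a well-defined, null-uniform p for a single site — the
  site-vs-site comparison the averaged trace alone cannot provide.
* No multiple-testing correction is applied across units or bins; every
  test is reported per unit as-is.

All surrogate procedures are bit-reproducible under a seed and invariant
to global time offsets.  Significance defaults to the 95th-percentile /
α = 0.05 convention; the threshold is configurable.

## Synthetic data

The generators define the test conditions for every stage:

* **Songs**: harmonic-stack syllables (fundamental + 1/h-weighted
  harmonics, optional linear FM, 2 ms cosine ramps) separated by 40 ms
  gaps; bouts hold 3 motif renditions with 120 ms inter-motif gaps and
  60 ms silent padding standing in for introductory notes; 40 kHz
  sampling.  The default motif has three syllables (650/950/1300 Hz, 90/
  70/60 ms, sweeps 0/−2/+3 Hz·ms⁻¹), loosely shaped like a zebra finch
  motif.  Distortion knobs — fractional pitch jitter, fractional duration
  jitter, syllable-drop probability, per-rendition sequence-shuffle
  probability, additive noise level — are applied independently per
  rendition; all-zero distortion renders a bit-exact copy, and the scalar
  level mapping (level 1 = 8% pitch jitter, 10% duration jitter, 20%
  drops, 30% shuffles, −20 dB noise) spans from faithful imitation to
  heavily degraded song.  Ground-truth segmentation is always emitted.
* **Spike trains**: inhomogeneous Poisson — a homogeneous baseline plus,
  per event, an independent Poisson component of the given amplitude over
  `[latency, latency+duration)`.  The injected response is rectangular
  rather than an alpha function so that latency and duration ground truth
  is unambiguous for recovery tests.
* **Antidromic trials**: Gaussian noise traces with an optional damped
  post-stimulus sinusoid (default 1 kHz, 4 ms decay) emulating an evoked
  antidromic volley.

What the synthetic data does *not* emulate: real zebra finch timbre and
syllable diversity (harmonic stacks only), introductory notes and call
intrusions, bout-length variability, bursting or refractory spike
statistics, electrode drift, or correlated noise across antidromic
trials.  Passing tests therefore demonstrate that the statistics recover
known structure under their own model assumptions — calibration, power,
monotonicity, oracle agreement — not that they are robust to every
pathology of real recordings.

## Numerical choices and degenerate inputs

Reference problem sizes used by the test suite and `scripts/acceptance.py`
are scaled to desk hardware: 200-shuffle bootstraps (1000 in production
use), 500-unit calibration runs, 10–20-syllable stereotypy runs against
full enumeration, 2-bout scoring at 4 distortion levels × 20 seeds.
Clips shorter than one window, stereo WAVs, non-positive sample rates,
mismatched frequency grids, pupil bouts shorter than twice the motif,
sub-2-trial antidromic sets and zero-variance baselines all raise
explicit errors; degenerate t-tests (all differences zero) return p = 1
flagged rather than NaN.

## Known limitations

* Acoustic features are one fixed recipe; no alternative pitch trackers
  or noise reduction are provided.
* The imitation score's absolute scale depends on τ and the feature set;
  comparisons are meaningful within one tutor/configuration, and the
  capacity anchors (0.197/0.104) apply to scores computed with a
  comparable configuration on real song.
* The latency/duration rule's duration estimate is upward-biased by
  late false-positive bins (see above) — a property of the consecutive-
  bin rule itself.
* A large below-band artifact present only in the test recordings (not
  the reference) can leak power into the 200 Hz–2 kHz band through the
  rectangular window's spectral tails and register as significant; drift
  common to both recording sets is handled correctly.  Multitaper band
  power would reduce the leakage at the cost of departing from the plain
  periodogram definition.
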