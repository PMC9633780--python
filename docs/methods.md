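# Methods

`phonoseq` studies a specific inference problem in the neuroscience of
speech: phoneme-evoked population responses last far longer (~300 ms) than
the phonemes that cause them (~78 ms), so at any instant a multichannel
recording superimposes the responses to roughly the last three speech
sounds.  How can phonetic *content* and serial *order* both be read out
from such a mixture?  The package implements the full analysis chain that
answers this question — confound removal, covariate-controlled decoding,
temporal generalisation, trajectory geometry, latency decoding, and a
sequence-reconstruction simulation — and a synthetic-data generator that
plants the two competing coding schemes (static vs dynamic) so every stage
can be validated against known ground truth.

## The synthetic study

### What the generator emulates

* **Phoneme stream.** Words are drawn i.i.d. from a small fixed lexicon
  (64 English-like words with corpus-style frequencies) and grouped into
  3–8-word sentences.  Phoneme durations are drawn from a normal
  distribution with mean 78 ms and SD 34 ms, truncated to [20, 136] ms —
  the truncation is symmetric about the mean so the nominal 78 ms mean is
  preserved exactly (a one-sided cut at 20 ms would bias it up by ~3 ms).
  Words are separated by uniform silences of 0–150 ms.
* **Planted code.** Each modelled binary feature is carried by a unit-norm
  random channel pattern.  The evoked response lasts 300 ms with a Hann
  (half-cosine rise/fall) amplitude envelope; responses of neighbouring
  phonemes add linearly, so epochs genuinely overlap.
* **Dynamics.** Pattern drift is a Givens-rotation cascade: channels are
  grouped into random disjoint pairs and each pair-plane rotates at
  `drift_rate` rotations/s, with per-plane rates jittered uniformly in
  [0.5, 1.5]× the nominal value.  The jitter prevents exact periodicity
  (a single shared rate makes every pattern recur after one full rotation,
  which produces artifactual parallel bands in the temporal-generalisation
  matrix and corresponds to no plausible neural code).  The pattern-overlap
  correlation falls like the mean plane cosine: at the dynamic preset
  (6.25 rot/s) it crosses zero ±40 ms from the training latency, so any
  given spatial pattern is informative for ~80 ms while the response lasts
  ~300 ms.  `drift_rate = 0` is the static limit.  A duration-scaled mode
  runs each phoneme's drift clock in units of its own duration (reference
  78 ms), making long phonemes evolve proportionally more slowly.
* **Confounds and noise.** An amplitude-envelope regressor (per-phoneme
  Hann bumps with random gains) and a smooth pitch proxy are injected
  through their own fixed random channel patterns; white sensor noise is
  added with the planted signal scaled to a configurable amplitude SNR.
  Presets: `clean` (SNR 2.0), `realistic` (SNR 0.05, which puts
  single-feature AUC in the 51–52 % regime typical of single-trial
  magnetoencephalography), `static-control` (SNR 2.0, drift 0).
* **Audio branch.** The pseudo-spectrogram carries the same features as a
  *static* pattern active only during each phoneme's acoustic extent —
  stationary cues that vanish with the stimulus.

### What it deliberately does not emulate

No volume conduction or forward model, no 1/f sensor-noise spectrum (white
noise default), no coarticulation between neighbouring phonemes, no
across-word predictive structure, and feature topographies that are random
rather than auditory-cortical.  Passing tests therefore certify the
*analysis chain* — that each estimator recovers what was planted, at
realistic overlap and SNR — not that real recordings contain such codes.

## Analysis chain

### Confound residualisation (TRF)

Each channel is modelled from the preceding 200 ms of envelope and pitch
(lagged ridge; both regressors and channels standardised before fitting).
The regularisation λ is selected from ten log-spaced values in
[1e−6, 1e+6] by the mean held-out Pearson correlation across channels over
three contiguous folds; residuals are formed from held-out predictions
(per fold, models fit on the complementary folds) transformed back to
original units, so no sample is residualised against an in-sample fit
(in-sample available via `held_out=False`).  Downstream analyses use only
these residuals.

### Epoching

Recordings are zero-phase FIR band-passed 0.1–50 Hz (1001 taps at
1 kHz by default; the low edge is nominal — synthetic data carry no
drift), decimated to 250 Hz, and cut −200…+600 ms around phoneme onsets:
exactly 201 samples.  No baseline correction anywhere.  Events too close
to an edge are dropped and reported.

### Feature space

31 modelled columns: 14 binary phonetic features (voicing; manner:
fricative, nasal, plosive, approximant, vowel; place: four vowel heights,
coronal, glottal, labial, velar), 3 information-theoretic covariates
(surprisal, cohort entropy, log sequence frequency), 8 boundary covariates
(word/syllable/morpheme on- and offsets, primary/secondary stress) and 6
positional covariates (phoneme-in-syllable/word/sentence,
syllable-in-word/sentence, word-in-sentence).  Binary columns are coded
±1; continuous columns are z-scored within the stream.  Cohorts restart at
each word onset: the continuation probability of phoneme *p* after a
word-internal prefix is the summed frequency of cohort words continuing
with *p* over the total cohort frequency (making it a proper conditional
distribution); surprisal is −log₂ of that probability, cohort entropy the
frequency-weighted Shannon entropy over the cohort after hearing *p*, and
sequence frequency the summed frequency of that cohort (log₁₀ by default;
the base is configurable as conventions differ).  Lagged design matrices
(`lag_features`) append the phonetic block of the k preceding phonemes,
padding missing history with 0 — the uninformative midpoint of the ±1
scale — rather than fabricating a phantom phoneme.

### Back-to-back (B2B) decoding

Per time sample and per random half-split of trials: (1) for each feature,
a ridge decoder across channels (α from 20 log-spaced values in
[1e−5, 1e+5], per-target, by efficient leave-one-out CV; channels
standardised by training-half statistics); (2) on the held-out half, each
decoded feature is regressed on *all* true features jointly (ridge, α by
CV, selected at the evaluated time sample).  The diagonal of the encoder
matrix — the beta — measures each feature's specific contribution, net of
its covariates.  Betas are averaged over 100 half-splits by default
(correlated features make single-split coefficients unstable); per-split
and per-timepoint RNG streams are derived from one master seed by counter,
so any timepoint is reproducible in isolation and results are independent
of execution order.  The encoder direction follows the published method
(decoded-on-true); the reverse is available via `direction=`.

Normalisation: the noise ceiling is the maximum over time of the betas
summed across features; dividing each beta timecourse by it yields
variance shares that sum to exactly 1 at the ceiling latency.

### Temporal generalisation (TG)

Decoders trained at each train time are evaluated (B2B encoder stage) at
every test time, giving a square surface whose diagonal reproduces the
per-timepoint timecourse exactly (same seed convention, checked to
1e−10).  The encoder α is selected at the diagonal and reused along the
row.  Group inference thresholds the across-subject t-map at t > 4 (the
Bonferroni-across-201-samples equivalent).  Derived statistics:

* **Diagonal vs rows.** Durations are longest contiguous suprathreshold
  runs.  The mean row duration is taken over informative rows only (rows
  with at least one suprathreshold cell); including decoders trained at
  latencies that never decode (e.g. pre-onset) would dilute the static
  code's row durations below its own diagonal and invert the comparison.
  The t statistic compares all per-train-time row durations against the
  single diagonal duration (df = 200 on the full grid).
* **Word clock.** Position Pk's surface is shifted by (k−1)·80 ms on the
  test axis; P−k aligns backwards from the average word offset.  Overlap
  between positions is the fraction of a position's suprathreshold cells
  also suprathreshold for at least one adjacent position; the interior
  variant excludes the first and last word positions, whose single
  neighbour arithmetically caps their overlap when only a few positions
  exist at desk scale.
* **Ridge angle.** PCA on the (test ms, train ms) coordinates of the
  suprathreshold cells, restricted to the largest 8-connected component
  (isolated false-positive cells otherwise tilt the axis); the angle of
  the first principal axis is 45° when test-time dynamics match training
  speed, < 45° when faster.  Cells are weighted equally (score weighting
  behind a flag).
* **Trial subsets.** Decoders are always trained on the full training
  half; only the evaluation trials are binned (duration quartiles,
  surprisal/entropy median splits on non-onset phonemes, word-length
  median split on onset phonemes), so bin differences reflect test
  responses, not training-set size.

### Trajectories and latency decoding

Interpretable topographies come from per-timepoint unregularised
least-squares decoders fit on all trials (no cross-validation; requires
more trials than channels).  Topography magnitudes (RMS across subjects,
absolute values — sign is ambiguous after RMS) are projected as cosine
distances onto unit-norm binary anterior/posterior and left/right sensor
masks.  The structure metric (range / mean-step × SD, averaged over the
two axes) is large for smooth far-ranging paths and small for jitter;
significance comes from shuffled-label null trajectories (default 100,
p floored at 1/(n+1)).

The latency decoder crops epochs to 100–400 ms, samples 16 equally spaced
timepoints (~53.3 Hz), collapses trials × latencies into observations,
standardises inputs and targets per training fold, and fits ridge
(α = 1) under 5-fold shuffled CV.  On information-free inputs every
held-out prediction collapses to the training mean, 250 ms.  Latency
decodability rises with drift rate in the regime where patterns stay
partially correlated across the crop window; at very fast drift the
interpolating linear readout needs a large norm, amplifying noise, so the
trend can reverse — the monotonicity property is therefore asserted on a
0–1.56 rot/s grid.  (A 16-point grid is used throughout; a 15-point grid
is a plotting convention.)

### Anagram simulation

All 24 orderings of {b, p, s, z} are synthesised from spatiotemporal
coefficient templates (voicing, plosive): each phoneme's feature-weighted
template, multiplied by a noise factor ~ Normal(1, σ) (σ = 0.1 default,
0 for ideal conditions — the smallest assumption consistent with a
multiplicative "noise factor"), shifted 100 ms per position and summed; 10
repetitions, sequences run back to back so history beyond four phonemes
resolves against the previous sequence.  Small-α ridge under 5-fold CV
reconstructs the feature vector of the phoneme h steps back; cosine
similarity between concatenated true and reconstructed vectors is compared
with a 10,000-fold label-shuffling null.  Lag 0 denotes the current
phoneme (its zero-noise similarity is 1 by linear recovery); an index
origin flag switches conventions.  With 300 ms templates and 100 ms
shifts, lags beyond 2 carry no overlap and fall to ~0; the lag curve is
non-increasing by construction.

### Group statistics

One-sample sign-flip cluster permutation test: t-timecourse across
subjects, clusters by threshold contiguity (default: two-tailed p = 0.05
critical t at df = n−1), statistic = summed cluster t, null = maximum
absolute cluster sum under random whole-subject sign negations
(exhaustive when 2ⁿ ≤ n_perm).  p-values use a 1/(n_perm+1) floor and are
scale invariant.  The paired two-condition test applies the same machinery
to condition differences.  Empirical type-I error at nominal 0.05 is
verified to lie in [0.02, 0.09].  Spearman correlations use midranks and a
label-permutation p.

## Numerical and scale choices

Desk-scale defaults used by the test suite and the reproduction script —
16–32 channels, 120–200 words (~400–700 phoneme epochs), 3–10 half-splits,
TG grids decimated 2–4× — were chosen so the full chain exercises every
code path in minutes on one CPU; the API defaults keep the full-scale
values (208 channels, 100 splits, 201-sample grids).  Six simulated
subjects at SNR 2 are enough for t > 4 group maps with the planted codes.
Degenerate inputs are errors, not silent NaNs: constant feature columns
(named in the message), empty cohorts, zero-probability continuations,
rank-deficient unregularised fits, single-class folds, epochs without
valid events.  The pipeline orchestrator (not the library) drops
feature columns that are constant in a sampled stream — a short stream may
simply lack, say, glottal phonemes — and logs them.

## Known limitations

Linear superposition with identical response shapes across phonemes;
no amplitude variation by stress or prosody; the toy lexicon's rigid
consonant-vowel structure makes some phonetic features degenerate within
a word position (position analyses in the tests therefore use planted
position-independent labels); the audio branch shares the channel-pattern
formalism rather than modelling a filterbank response; cluster inference
is temporal only (no channel adjacency).
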