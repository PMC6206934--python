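# Methods

## The decoding problem

`plvdecode` implements a phase-synchrony decoding stack for cued and
self-paced motor-imagery (MI) brain-computer interfacing.  The working
hypothesis is that imagining a left- or right-hand movement transiently
couples the phases of band-limited EEG rhythms between specific sensor
pairs, and that the *pattern* of pairwise phase locking — rather than signal
amplitude — carries the decodable information.

The stack runs, in order: band-limited preprocessing, phase-locking-value
(PLV) connectivity (static and sliding-window), weighted-graph network
metrics, permutation-thresholded feature screening, linear-SVM direction
decoding (static and time-indexed), a time-lagged SVM ensemble producing a
streaming classification index, and a radial-basis-kernel "switch" that
detects MI events in that index without an external trigger.  Cohort-level
contrast statistics (patients vs controls) operate on the same connectivity
patterns and network metrics.

## Preprocessing

Continuous recordings are band-pass filtered with third-order Butterworth
filters applied forward-backward (`scipy.signal.sosfiltfilt`), i.e. in
zero-phase mode, *before* epoching so filter transients never touch trial
edges.  The wideband signal (0.5–45 Hz) is average-re-referenced across the
good channels (bad channels are supplied by the caller; their
identification by visual/spectral inspection is a manual step outside this
package — a variance-based z-score flagger is provided as a convenience
only).  Re-referencing happens once, on the wideband signal, before the
split into the seven canonical rhythms δ(1–4), θ(4–8), α1(8–10), α2(10–13),
β1(13–20), β2(20–30), γ(30–45) Hz; since both operations are linear their
order does not affect the result.

MI epochs run from cue onset to onset + 5 s; the rest recording is cut into
20 consecutive non-overlapping 8-s baseline trials (a 3-min recording
accommodates exactly 20 × 8 s with margin).

## PLV connectivity

For a band-limited trial the per-channel instantaneous phase φ_k(t) is the
angle of the analytic signal (Hilbert transform).  The phase locking value
of a channel pair over an integration window of n samples is

    PLV(x_k, x_r) = (1/n) | Σ_t exp(i(φ_k(t) − φ_r(t))) |,

1 for perfect locking and ~√π/(2√n) in expectation for independent phases.
All pairs are computed in one pass as the Gram matrix of time-averaged unit
phasors, which makes the full [N×N] pattern one complex matrix product; a
per-pair loop is kept in the test suite as the oracle.  The symmetric
matrix with unit diagonal is vectorized as vec(W): the elements W_kr with
r < k scanned k-major, giving N(N−1)/2 features (1830 for 61 sensors); an
index map pair↔vec position is exported.

Sliding-window sequences vec(W[τ]) use the cycle criterion — the window
spans 3 cycles of the band's lowest frequency (0.375 s for α1, ~0.231 s for
β1) — advanced by 350 ms for cued decoding and 20 ms for streaming
analyses.  Phase is extracted once per trial on the full epoch and windows
slice the phase series, avoiding per-window Hilbert edge effects.  Windows
are truncated at the trial end, so N_τ = ⌊(L − T_window)/step⌋ + 1.

A physical limitation worth knowing: after band-pass filtering, *any*
signal decorrelates no faster than the band width allows (coherence time
≈ 1/bandwidth).  For narrow rhythms such as α1 the cycle-criterion window
is shorter than this coherence time, so short-window PLV between
independent channels sits close to 1 and carries almost no contrast; bands
whose width is comparable to their lower edge (β1 and above) are the useful
regime for time-resolved analyses, and the synthetic recovery studies
below therefore read out β1.

## Network metrics

Node strength is the off-diagonal row sum of W.  Efficiency follows the
Latora–Marchiori weighted formulation on distances d_kr = 1 − w_kr with
Dijkstra shortest paths (scipy.sparse.csgraph): global efficiency is the
mean inverse shortest-path length over ordered pairs; local efficiency is
the mean over nodes of the efficiency of the subgraph induced by each
node's neighbors (w_kr > 0; intra-subgraph edges only; nodes with fewer
than two neighbors contribute 0).  Weights are capped at 1 − 10⁻⁶ before
the distance transform so a perfectly locked pair cannot create a
zero-length path; disconnected pairs contribute 0 through 1/l.  A printed
formulation that sums LE(k) over r ≠ k while dividing by N is read as the
standard mean over nodes of LE(k).

## Feature screening

Static screening scores every coupling with the absolute standardized
two-sample Wilcoxon rank-sum statistic |z| (tie-corrected; an all-tied
feature scores 0) and keeps the top k = 10, ties broken by ascending pair
index.

Dynamic screening scores every coupling at every latency, Score(r, τ).  A
global threshold thr_99.9% is the 99.9th percentile of the pooled null
scores obtained from n_rand = 100 random re-partitions of the trials into
two groups of the original sizes, marking couplings discriminative at
p < 0.001.  The binary exceedance mask is sieved row-wise with a running
median whose length is the smallest odd w with (w−1)/2 · step ≥ 100 ms
(11 taps at 20 ms, 3 at 350 ms), eliminating supra-threshold runs shorter
than the ~100 ms persistence floor; Profile(r) counts the surviving
latencies per pair.

The final feature set aggregates this profile over n_boot = 30
within-class bootstrap resamples of the trials (resampling within class
keeps both group sizes and avoids degenerate single-class resamples at
n = 10).  The permutation threshold is computed once from the observed
data and reused across resamples — the null being estimated does not
change, and recomputing it per resample would multiply the permutation
cost thirtyfold.  A pair is selected when its average profile exceeds the
selection floor max(0.5, 0.1 s/step): on coarse grids this is the original
"more than half a latency on average" rule; on dense grids it requires
average persistence of at least one 100-ms floor, which keeps chance
survivors out of the 245-latency streaming grid.  An empty selection warns
and falls back to the static top-10 ranking of time-averaged patterns.

## Direction decoding

The direction decoder is a maximum-margin linear SVM (C = 1, features
standardized with training statistics; no hyperparameter tuning, for
determinism).  Its signed confidence is 2·P(right) − 1 ∈ [−1, 1], with
P obtained from a logistic sigmoid fitted on the training-set decision
values (Platt-style).  The sigmoid is moderately regularized (C = 1) so
that confidence magnitude stays graded on separable training sets — a
saturated sigmoid would assign full confidence to arbitrary out-of-class
(e.g. resting) patterns and destroy the MI-vs-baseline contrast the switch
relies on.

Static scenario: leave-one-out cross-validation over the 2N = 40 trials
with the top-10 selection re-run inside every fold (verified by
instrumentation: the fold holding out an artifact-carrying trial never
selects the artifact feature).  Time-indexed scenario: the bootstrap
selection is computed once, outside LOOCV (its temporal-consistency logic
needs all trials), and one "instantaneous" SVM per latency is trained and
LOOCV-scored on vec(W[τ]) restricted to the fixed feature set.

## SVM ensemble and the self-paced switch

Ensemble members are chosen from the time-resolved accuracy curve: every
latency within 90% of the curve maximum is a candidate (a noisy curve
contributes its local peaks; a curve saturated at its ceiling contributes
the whole plateau — consecutive but non-colliding members are exactly the
intent), kept greedily in accuracy order subject to (a) pairwise lag
separation of at least one window width and (b) hyperplane-normal cosine
similarity < 0.95, so members define genuinely different separating
hyperplanes.  An upper lag bound keeps the readout trace long enough for
switch training.  The streaming classification index reads each member at
its own lag:

    z_ensemble(t) = (1/M) Σ_i z^i(t + τ_sel_i).

For the trigger-free detector, 10 trials per class ("left", "right",
"rest") train the two-stage model: stage one (MI trials only) runs feature
selection, the time-resolved bank and ensemble assembly; stage two derives
z_ensemble traces for all 30 training trials and fits an RBF-kernel SVM on
0.5-s trace segments — 5 evenly spaced segments per MI trial inside
[onset + 0.2 s, onset + 2.0 s] (100 MI-event segments at the study design)
against an equal number drawn at random positions from the rest traces.
At test time consecutive segments are scored; runs of confidence above 0.5
merge into single detections stamped with the sign of the index at the
flag.  A detection inside a rest trial is a false positive, an MI trial
without any detection a false negative; both counts are referenced to the
total number of test trials, and rates are averaged over Monte-Carlo
splits (10 train / 10 test per class, re-fitting the full two-stage model
per split).

## Group statistics

Subject-averaged coupling patterns, restricted to the sensors good in all
subjects, are compared pair-by-pair with two-sample Wilcoxon rank-sum
tests under Benjamini–Hochberg FDR at α = 0.05, with the median difference
med(A) − med(B) recording direction.  Per-subject network-metric triads
(mean strength, GE, LE per band) are compared with rank-sum tests under
Bonferroni correction across the full metric × band family at α = 0.01.
A generic one- or two-tailed rank-sum utility covers ad-hoc contrasts
(e.g. best-band accuracies between cohorts).

## The synthetic-data generator

Real recordings for this paradigm are not publicly deposited, so every
downstream stage is exercised on seeded synthetic subjects emulating the
study design: 61 channels (10-10 montage names) at 256 Hz — reduced
montages keep a prefix of the same label list — 20 cued trials per class
(3 s fixation, 5 s imagery, 2 s inter-trial), and a 180-s rest recording.

Each channel sums seven narrowband oscillators, one per rhythm, realized
as cos(φ(t)) with φ a random-walk-perturbed linear phase at the band
center; increments are sized so the oscillator linewidth is about half the
band width, and each component is confined to its band with a sharp
spectral mask (a random-walk phase has Lorentzian tails that would
otherwise leak across rhythms).  Amplitudes follow a 1/√f law; 1/f-shaped
Gaussian noise is added at a configurable total-power SNR (default 10 dB).

A coupling schedule plants class-conditioned, event-locked synchrony: for
a scheduled pair, band, class and latency window, the band component of
both channels becomes the power-normalized mixture
(1 − κ)·cos(φ_own) + κ·cos(φ_latent + jitter) with a shared latent
oscillator, mixing weight κ ∈ [0, 1], per-channel Gaussian phase jitter,
and a 0.1-s raised-cosine on/off ramp for waveform continuity.  κ = 1 with
zero jitter reproduces PLV ≈ 1 in the scheduled window.  Entries are
applied in order, so schedules use channel-disjoint pairs per band (a
shared channel would have its lock re-mixed by a later entry).  All
randomness derives from one seed through spawned sub-streams; output is
bit-reproducible.

The default schedule couples four channel-disjoint contralateral
sensorimotor pairs per class (around C4/FC4/CP4 for left imagery,
C3/FC3/CP3 for right) in α1 and β1, window 0.5–4.0 s after onset,
κ = 0.8, jitter 0.1 rad.  These defaults were designed so that the
documented recovery regime (κ = 0.8, 10 dB SNR, 20 trials/class) is met
in β1: static LOOCV ≥ 0.9 and a time-resolved accuracy curve peaking
inside the planted window.

What the generator does *not* emulate: volume conduction and field spread
(channels are independent except through the average reference), eye/EMG
artifacts, non-stationary background, inter-subject variability, and
realistic scalp topographies.  Passing recovery tests therefore show that
the algorithms detect and decode planted phase coupling at realistic
sample sizes and SNR — not that real EEG contains such coupling.

## Problem sizes used in the test suite

Structural and oracle tests run at 8 channels or on random small matrices.
Parameter-recovery tests use a 16-channel subject with the default
coupling layout (seed 7) analyzed in β1 — static LOOCV, bootstrap
selection at the 350-ms step, and the time-resolved curve.  The self-paced
Monte-Carlo check uses a deliberately *strongly separable* subject — 32
channels, 8 planted pairs per class and band, window 0.2–4.5 s, jitter
0.05, 20 dB SNR, κ = 0.8 — evaluated over 2 splits with n_boot = 15 and
n_rand = 50; this is the package's synthetic stand-in for the
best-performing patients, for whom the published detector operates at a
few percent error.  Full-scale parameters (61 channels, 100 splits,
n_rand = 100, n_boot = 30) remain the library defaults.

## Numerical choices and degenerate inputs

* PLV windows need ≥ 2 samples; constant channels have undefined phase and
  are flagged with a warning.
* Weights are capped at 1 − 10⁻⁶ before the distance transform; w = 0 means
  "no edge".
* Static selection breaks score ties by ascending pair index; ensemble
  candidate ties by earlier latency.
* The running median uses zero padding at the sequence ends, so a run
  touching the trial boundary is treated as bounded by sub-threshold
  latencies.
* LOOCV with fewer than 4 trials, single-class training sets, empty
  feature sets, streams shorter than the largest ensemble lag, and rest
  recordings too short for the requested baseline trials all fail fast
  with explicit errors (the short stream warns and returns an empty
  trace).

## Known limitations

* EDF files are read (via mne); writing is native-format only.
* The similarity test between ensemble members is a cosine rule on
  hyperplane normals — the underlying publication does not specify one.
* The switch-training interval bounds (0.2–2.0 s) are configurable
  defaults; the source figures do not print them.
* Sensor-space PLV is not corrected for volume conduction or reference
  leakage; at small montages the average reference visibly couples
  channels (the group statistics and screening thresholds absorb this,
  but absolute PLV levels are reference-dependent).
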