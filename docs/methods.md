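# Methods

## Signal model

Every epoch is modelled additively: `x_j(t) = s(t) + n_j(t)`, where `s(t)`
is the subject's evoked response, present only in target epochs, and
`n_j(t)` is background noise, independent across epochs and channels.
Coherent averaging of M target epochs estimates `s(t)` with residual noise
standard deviation shrinking as `σ/√M`; this law is verified by Monte-Carlo
in the test suite.

The simulated evoked response is a Gaussian bump parameterized by peak
latency (ms), peak amplitude (µV) and FWHM width (ms), projected through a
per-channel topography vector normalized to max |w| = 1. A Gaussian was
chosen because it is smooth, strictly unimodal, and fully determined by the
three parameters that dominate P300 variability across people; no claim is
made that real P300 morphology is Gaussian. The bump is truncated to zero
before stimulus onset so the baseline segment is signal-free by
construction. Nontarget epochs carry no evoked component at all — a
conservative null that makes chance-level behaviour exactly chance.

Background noise is 1/f^α-shaped Gaussian noise (α = 1 by default, the
canonical EEG spectrum), produced by frequency-domain shaping of white
noise with an analytically normalized gain so the time-domain standard
deviation equals `noise_sd` in expectation without per-epoch rescaling
(which would break independence). An optional 50 Hz sinusoid of random
phase can be added per epoch to exercise the notch-filter path; it is off
by default.

## Cohort structure

Subjects are drawn hierarchically: cluster centers first (between-cluster
standard deviations for latency, amplitude, width, topography), then
per-subject perturbations (within-cluster SDs). Cluster assignment is
round-robin, keeping cluster sizes balanced, and is recorded in the
archetype table as recoverable ground truth. `cluster_latencies` can pin
the center latencies exactly, which the tests use to build cohorts with
known separation. Latencies are clipped to [120 ms, window end − width/2]
so the bump stays inside the epoch.

Defaults: base latency 360 ms, amplitude 5 µV, width 150 ms FWHM,
`noise_sd` 10 µV — a single-trial amplitude-SNR of 0.5, typical of the
regime where single-epoch detection is imperfect but averaged ERPs are
clean. Between-cluster SDs (40 ms, 1.5 µV, 20 ms, 0.15) and within-cluster
SDs (10 ms, 0.5 µV, 8 ms, 0.05) encode the qualitative observation that
inter-subject differences are large relative to within-subject session
variability; they are simulation knobs, not estimates fitted to any
recorded population. A "matrix-like" variant triples the between-subject
dispersion to emulate the larger individual differences reported for
matrix spellers; it is an emulation, not a physiological model.

Session structure follows the speller paradigm: each *round* presents all
`n_symbols` symbols (A–Z order by default) for 200 ms with a 100 ms gap
(300 ms SOA); 5 rounds form a *trial* for one target letter; 8 trials form
a *block*; a full session has 20 blocks — 20,800 epochs, 800 of them
targets. Target letters are drawn per block without replacement. Epochs
are generated directly at the 200 Hz analysis rate over a −200..+800 ms
window; continuous-record synthesis is out of scope, so acquisition-rate
effects enter only through the preprocessing module's own tests.

What the generator does **not** emulate: eye/muscle artifacts, channel
cross-correlation of real volume conduction, non-stationarity across a
session, latency jitter across single trials, or any nontarget evoked
activity. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under the stated statistical assumptions,
not their performance on recorded EEG.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (0.1–30 Hz default) via
forward–backward filtering; decimation by integer factor (2000 → 200 Hz
default) with event-index rescaling, relying on the band-pass as the
anti-alias stage; epoching over half-open windows with per-epoch baseline
subtraction (−200..0 ms mean); channel selection to the six analysis
channels FZ, CZ, PZ, O1, O2, OZ. Epoch sample 0 is the window start;
stimulus onset sits at `rate·|start|/1000`. Baseline correction is
idempotent, and filtering+decimation commute with epoching away from
record edges — both are tested. Ear re-referencing and a 50 Hz notch are
optional stages; synthetic cohorts are generated reference-free and skip
them.

## Similarity and donor ranking

ERPs enter both similarity metrics as the target-class mean restricted to
the 0–800 ms post-stimulus segment, channels concatenated in channel
order. The baseline segment is excluded deliberately: after baseline
correction it is near zero for every subject and would inflate all
similarities. Whether one, six, or 64 channels should enter the comparison
is an open choice; the six-channel concatenation is this package's
documented default and is configurable via `segment`/channel selection.

The match statistic binarizes the cosine matrix at a threshold (default
0.5) with a **strict** inequality, excludes the diagonal, and counts
matches per subject. The CAR ranking sorts donors by descending Pearson r
(computed with n−1 sample standard deviations), ties broken by ascending
subject id so output is deterministic. Zero-norm or zero-variance ERPs
raise errors rather than scoring 0 — a silent zero would corrupt rankings.

## Cross-subject evaluation protocol

For each test subject in turn: the first `calibration_blocks` (default 2)
blocks are split off and used *only* to build the calibration ERP that CAR
ranks against; donors are the remaining subjects, represented by their
full-session ERPs and epochs. The LDA is trained on the pooled epochs of
the selected donors (never the test subject) and scored on the test
subject's non-calibration epochs (never the calibration epochs). Both
exclusions are asserted at run time and the selected donor lists are
recorded in the result's provenance. The random model repeats donor
selection `reps` times (default 10) with sub-seeds derived from the main
seed; CAR is deterministic given the cohort.

Features are per-epoch means over consecutive 50 ms bins within 0–800 ms
on the six analysis channels — 96 dimensions — which keeps the pooled
covariance well-conditioned at small donor counts. The classifier is LDA
with the lsqr solver and Ledoit–Wolf analytic shrinkage by default; when
the within-class covariance vanishes entirely (noiseless cohorts) the
discriminant direction degenerates to the class-mean difference, which is
the correct Σ→0 limit and is substituted explicitly. The 1:25
target:nontarget imbalance is left as-is since AUC is rank-based.

Model comparison follows the protocol of a per-sample Kolmogorov–Smirnov
normality check (against a normal with the sample's mean and SD) followed
by a two-sided paired t-test on per-subject AUC differences. Differences
that are constant to machine precision are reported as degenerate rather
than as p = 0.

## ITR

`ITR = [log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))]/T` with `P log₂P → 0`
at the endpoints by continuity. Selection time T is defined as pure
stimulus time, `rounds × symbols × SOA` (0.65 min at the default
paradigm), with no inter-trial pauses; any other T can be passed directly.
Accuracies below chance raise an error rather than produce a negative
rate. Symbol selection sums decision scores per candidate symbol across
the rounds of a trial and takes the argmax, ties resolved to the
alphabetically first symbol.

## Problem sizes

Full-study scale (58 subjects × 20 blocks) is supported but deliberately
not used by the test suite or the acceptance script; they run the same
code on 8–24-subject cohorts with 2–3 blocks per session, sizes at which
every qualitative effect of interest (cluster recovery, the CAR-vs-random
ordering, chance floors) is already stable and a full run completes in
about a minute. The headline comparison uses 24 subjects in two latency
clusters (300 vs 460 ms), N = 11 donors (cluster size − 1), one
calibration block, five random-model repetitions.

## Known limitations

- Synthetic cohorts only; no claims transfer to recorded EEG without
  validation on real data (EDF ingestion is provided for that purpose).
- The "order model" sometimes discussed alongside random selection is not
  implemented; only random and CAR donor selection are compared.
- Donor epochs are pooled without per-subject normalization by default;
  per-donor z-scoring and nontarget subsampling exist as opt-in flags and
  are excluded from the headline protocol.
- The EDF writer is minimal (16-bit, 1 s records, µV) and intended for
  round-trip testing and interchange, not archival fidelity.
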