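# Methods

## Decoding model

A block is decoded from six binary target-vs-standard classifications.
Each button's five trial epochs are averaged; an averaged sample is a
channels × window matrix (8 × 150 at the defaults: 8 channels, 150–300 ms
at 1000 Hz).  One pair of CSP filters is fit on the supervised training
set: per-sample covariances are normalized to unit trace (removing
per-trial gain), averaged per class into Σ₁ (target) and Σ₂ (standard),
and the generalized eigenproblem Σ₁w = λ(Σ₁+Σ₂)w is solved with a small
ridge term (ε = 1e-6 of the mean diagonal) on the composite matrix.
Eigenvalues lie in [0, 1]; the eigenvectors of the largest and smallest
eigenvalue are the selected pair, their signs fixed so the
largest-magnitude coefficient is positive.  Features are the natural-log
variances of the two projections.  The classifier is an RBF-kernel SVM at
library-default hyperparameters with Platt-type posterior calibration
(deliberately untuned).  A block's predicted button is the argmax of the
six target-class posteriors, ties broken to the lowest button index.

## Calibration loop

The test session is processed in segments of `interval_blocks` (default
4).  Each segment is decoded with the current model and *then* used for
calibration, so no block is ever decoded by a model that saw its own
segment.  The candidate pool is all six button-averages per block; the
resulting 1:5 class imbalance of additions is accepted and visible in the
audit trail.  Self-labeling combines the SVM posterior with a from-scratch
two-cluster fuzzy C-means (fuzzifier m = 2, Euclidean distances, tolerance
1e-6, ≤ 300 iterations) initialized at the supervised class centers of the
current training set; its clusters are mapped to task labels by the
distance-minimizing assignment of cluster centers to class centers, which
reduces to nearest-center matching whenever that is consistent and
resolves the degenerate both-near-one-center case.  A candidate is
harvested under the fusion rule iff the two labels agree and both
confidences strictly exceed δ (default 0.75); `svm_only` / `fcm_only`
variants threshold a single confidence.

Timestamps count recency (newest = 1).  After each harvest the set is
clipped to capacity M = 250 by removing timestamps > M, with one guard:
a class that clipping would reduce below `min_per_class` (default 2)
keeps its newest members, displacing the oldest kept samples of the other
class.  Without the guard the clip rule alone can empty a class and make
retraining impossible.  After clipping, timestamps are renumbered
1..size.  A cycle that changes nothing (e.g. δ = 1) leaves the decoder
untouched, so disabling selection is bit-identical to the fixed pipeline.

CSP filters are fixed after initial training by default
(`refit_csp=False`); setting `refit_csp=True` refits them each cycle on
the stored raw windows of the (self-labeled) training set and recomputes
all stored features.  Refitting matters when the nonstationarity is
spatial, since fixed filters then slowly stop seeing the signal.

## Synthetic sessions

The generator emulates the six-button speller paradigm (140 ms motion +
60 ms gap per button, 300 ms inter-trial pause ⇒ 1.5 s trials, 7.5 s
five-trial blocks) with a known uniformly random target button per block.
A target epoch is the sum of three Gaussian components — P1 (+3 µV,
130 ms, σ = 20 ms), N2 (−6 µV, 180 ms, σ = 25 ms), P2 (+4 µV, 240 ms,
σ = 30 ms) — projected through a fixed occipito-parietal topography, plus
1/f Gaussian noise (default 10 µV per channel); a non-target epoch is
noise only.  All randomness derives from integer seeds via per-epoch
`SeedSequence` keys, so sessions are bit-reproducible and round-trip
exactly through the CSV/JSON fixture format.

The noise level was chosen so that the fixed pipeline decodes a stable
session at an accuracy typical of good speller subjects (~90%); above
~14 µV the 50 µV artifact-rejection threshold starts discarding most
epochs and the pipeline degenerates, which brackets the usable range.

State drift is a per-block process d(b) = magnitude · g(b) with g linear,
random-walk or a step, applied to any subset of three aspects: gain
(amplitudes × (1 − d): positive drift fades the response, as in a
fatiguing subject), latency (+ d·50 ms) and topography (convex mixing
toward an alternate centro-parietal pattern, renormalized).  What the
generator does **not** emulate: real artifact morphologies (blinks,
muscle), inter-subject variability of component shapes, trial-to-trial
latency jitter within a block, or correlated noise across channels.
Passing tests therefore show that the calibration mechanics behave as
specified under controlled drift, not that the accuracy gains transfer
quantitatively to real recordings.

## Drift-recovery study

The packaged study (`experiments.drift_recovery_study`) treats each seed
as a subject: a stable 36-block training session plus a 36-block test
session with linear drift of 0.02/block applied to latency and topography
— the information-*preserving* nonstationarities a recalibrated decoder
can track.  Pure gain loss was excluded deliberately: it destroys
signal-to-noise itself, and no amount of recalibration recovers it (the
strategies tie).  The study configuration sets `refit_csp=True` because
the injected drift is partly spatial.  All four strategies decode the
same preprocessed data per seed, so comparisons are paired; 20 seeds run
in well under a minute.

Observed behaviour (20 seeds): fusion calibration recovers roughly 3
accuracy points over the fixed baseline, and its harvest precision C sits
far above the fCM-only labeler.  One caveat is reported honestly: the
SVM-only labeler's C is marginally (≈0.01) *higher* than fusion's in this
synthetic regime.  Both labelers confidently agree on the same systematic
errors (strongly drifted targets that sit deep inside the standard
cluster), so the agreement veto removes correct-but-moderate-confidence
candidates while those shared errors survive.  The fusion rule still
wins where it matters — accuracy — because vetoing fCM-disagreeing
candidates curbs the *volume* of mislabeled additions per cycle.

## Numerical choices

- Bandpass: 4th-order Butterworth, 0.5–10 Hz, applied forward-backward
  (zero phase) as second-order sections — the transfer-function form is
  numerically unstable for so narrow a band at 1000 Hz.  The strict
  out-of-band/in-band power ratio converges to ≈0.05 (transition bands
  included); beyond one octave of the band edges suppression is complete.
- Artifact rejection is strict (> 50 µV rejects, exactly 50 kept) and
  applied to raw epochs before filtering.
- Window convention: half-open [150, 300) ms, 0-based samples, onset at
  0 ms ⇒ 150 samples at 1000 Hz.
- fCM distance ties (a point exactly on a center) give that cluster full
  membership.  Fewer than two distinct points is a degeneracy error; a
  degenerate segment skips fCM and contributes zero fusion selections
  that cycle.
- Report tables round to one decimal, half away from zero.
- The paired strategy comparison uses the two-sided paired t-test;
  identical vectors (zero-variance differences) are reported as not
  significant rather than undefined.
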