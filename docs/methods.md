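# Methods

`soabci` is an offline analysis pipeline for a six-direction spatial-auditory
oddball brain-computer interface (BCI), together with the synthetic-EEG
generator that makes every stage testable without human recordings. This
note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic results do and do not show.

## Experimental design being modeled

A *sub-trial* is one 100-ms white-noise burst presented from one of six
virtual sound directions (±30°, ±90°, ±150°). A *trial* is six sub-trials
covering every direction exactly once in pseudorandom order; a *block*
fixes one attended (target) direction, so each trial contains exactly one
target and five non-targets. Consecutive sub-trial onsets are separated by
the stimulus onset asynchrony (SOA); the conditions of interest span
200–1,100 ms. EEG is 64 channels (10-10 names of the BioSemi 64 cap) at
256 Hz.

`oddball.generate_schedule` draws each trial's direction order as an
independent uniform permutation of the six directions. An optional
constraint resamples a permutation when a trial would open with a target
immediately after a trial that closed with one; it is **off by default**
because nothing in the design requires it. Block target assignments are
concatenated shuffled permutations of the six directions, so counts are
exactly balanced whenever the number of blocks is a multiple of six.
Blocks are laid out sequentially with a configurable inter-block gap
(default 60 s, the ~1-min rest between blocks; simulated cohorts compress
it to 2 s since no task events occur there). A consequence of the
permutation design is that the expected target-to-target onset interval is
6 × SOA — 1.2 s at the 200-ms SOA — which the tests verify by simulation.

Behavioral button presses are scored against per-target response windows:
[onset + 150 ms, next onset) for SOA ≥ 500 ms, and [onset + 150 ms,
onset + 600 ms) for shorter SOAs (reaction times of 400–500 ms exceed
short SOAs, so responses spill past the next stimulus). Presses are
assigned greedily, earliest window first, each press creditable to at most
one target.

## Synthetic EEG generator

Each sub-trial adds Gaussian-in-time component bumps scaled by a
per-channel scalp gain vector; everything superposes linearly, and
stationary background noise is added. Defaults:

| component | latency | width (FWHM) | amplitude | scalp map | applies to |
|---|---|---|---|---|---|
| N100 | 98 ms | 30 ms | −3 µV | frontal-central | all sub-trials |
| P200 | 203 ms | 40 ms | +4 µV | frontal-central | all sub-trials |
| P200 target reduction | 203 ms | 40 ms | −1.5 µV | frontal-central | targets |
| P300 | 375 ms | 120 ms | +6 µV | central-posterior | targets, SOA-gated |

The latencies are the canonical component latencies of this paradigm
(98/203/375 ms). `width_s` is interpreted as the bump's full width at half
maximum: with the half-width-at-half-maximum reading the default P300
(σ ≈ 102 ms) would bleed far enough into the 170–260-ms window to displace
the P200 peak, contradicting the latency-recovery property the templates
must satisfy. Scalp maps are plain gain vectors (core 1.0 / neighborhood
0.6 / elsewhere 0.15 over named channel groups), so no electrode-geometry
math exists anywhere.

**SOA-dependent P300 attenuation** encodes the refractory
target-to-target-interval effect: gain 1 for SOA ≥ 400 ms, 0.6 at 300 ms,
0.3 at 200 ms, linearly interpolated, monotone non-decreasing. The true
per-SOA amplitudes are only ever plotted, never tabulated, in the study
this emulates; these values are explicit artifact choices and are held
fixed.

**Background noise** is per-channel AR(2) (coefficients 1.45, −0.55,
variance-normalized) with a shared common component giving pairwise channel
correlation 0.3, standard deviation 8 µV — a band-limited ongoing-EEG
magnitude against which a single-trial 6-µV P300 is detectable but noisy,
which is the regime the decoder is meant to exercise. White and 1/√f
("pink") models are available; white noise is used in unit tests where
spectral shape is irrelevant. No ocular or motion artifacts are injected
(artifact removal is outside the pipeline's scope).

**Cohorts**: per participant, one multiplicative log-normal amplitude
factor per component (sd 0.2) and one additive Gaussian latency shift
(sd 15 ms) are drawn once and shared across that participant's SOA
conditions, so between-participant variability is consistent within
participant. All seeds derive from one master seed through
`numpy.random.SeedSequence` spawn keys.

What the generator does **not** emulate: non-stationary and non-Gaussian
EEG, eye/muscle artifacts, trial-to-trial latency jitter, habituation over
a session, volume-conduction-accurate topographies, and any genuine
attention mechanism. Passing tests therefore show that the analysis code
is correct and behaves sensibly under a plausible linear-ERP model — not
that the paradigm reaches any particular accuracy on real recordings.

## Preprocessing

Band-pass 0.1–8 Hz, implemented as a 4th-order Butterworth applied
forward-backward (`scipy.signal.sosfiltfilt`) on the continuous recording,
so it is zero-phase and latencies are not shifted. The pass band is the
conventional P300 band: the source description names 0.1 Hz and 8 Hz as
"low-pass" and "high-pass" cutoffs, which taken literally would delete the
signal of interest, so the band-pass reading is used. Edge padding spans
six time constants of the 0.1-Hz edge (6/0.1 s) so the slow transient
never reaches the data.

Epochs are [onset, onset + 1 s) — 256 samples — one per sub-trial; at short
SOAs they overlap and shared samples are duplicated. Baseline is the mean
of the last 100 ms before onset; at 256 Hz that is 25.6 samples, rounded up
to 26 (configurable; the ambiguity is a documented choice). Decimation
averages every 10 samples: 25 bins, the trailing 6 samples dropped rather
than forming a partial 26th bin, so bins are identically distributed.
Features are the channel-major flattening, 64 × 25 = 1,600 values.

## ERP statistics

Class averages per participant; grand averages are unweighted means of
participant means. Paired two-sided t-tests run element-wise across
participants over time samples (m = 256) or channels (m = 64), with
Benjamini–Hochberg step-up FDR at q = 0.05 (via
`statsmodels.stats.multitest`; an independent brute-force step-up oracle
checks it in the tests). Zero-variance paired differences with a non-zero
mean get flagged NaN p-values and are excluded from the FDR family —
degenerate simulations should not produce spurious certainty; exactly
identical pairs give t = 0, p = 1. Component latencies are the extrema of
the Pz grand-average difference wave in 80–180 ms (N100, minimum),
170–260 ms (P200, maximum) and 300–500 ms (P300, maximum).

## Decoder: regularized Fisher discriminant + PSO

The binary target/non-target classifier maximizes

J(w) = ⟨w, m_t − m_nt⟩² / (wᵀ S_w w + λ‖w‖²)

with m_t, m_nt the class means and S_w the pooled within-class covariance
(1/(n−2) normalization; λ added to the diagonal unscaled, matching the
λ‖w‖² penalty). The maximizer up to positive scale is
w = (S_w + λI)⁻¹(m_t − m_nt); the implementation fixes the scale by that
closed form (no normalization). The projection itself has no offset, but
the "score 0 = on the hyperplane" decision rule needs one, so the midpoint
bias b = −wᵀ(m_t + m_nt)/2 is used and the score is wᵀx + b (positive ⇒
target). With λ = 0 and non-singular S_w this is classical Fisher LDA;
with 1,600-dimensional features and a few hundred training epochs S_w is
singular and λ = 0 raises an explicit error.

λ is selected per training split by global-best particle-swarm
optimization over log₁₀λ ∈ [−6, 3]: 20 particles, 30 iterations, inertia
0.72, cognitive = social = 1.49, velocity clamped to half the domain
width, reflecting boundaries. These are standard constricted-swarm
settings chosen here as package defaults (the original method's PSO
details are not public). The PSO fitness is the mean **balanced** accuracy
(threshold 0) over 5 stratified inner folds — plain accuracy has a
degenerate 5/6 optimum ("everything is a non-target") under the 1:5 class
imbalance. A grid-scan oracle bounds the PSO result in the tests.

Numerical core: each training fold's scatter is eigendecomposed once —
dense `eigh` of S_w when n ≥ D, otherwise a thin SVD of the centered data
(the orthogonal complement, where S_w acts as zero, is handled in closed
form) — after which w(λ) costs two matrix-vector products for any λ. This
is exact, and it is what makes a PSO with hundreds of λ evaluations cheap.

## Identification, accuracy curves, utility

Trials are split into 5 folds stratified by target direction (shuffled
within direction, dealt round-robin with a rotating offset so fold sizes
differ by at most one). Every sub-trial is scored exactly once, by the
model of the fold that held it out; a reconstruction test verifies no
training leakage.

For n-trial averaging, trials within (fold, target direction) are grouped
in (block, trial) order into **disjoint** consecutive sets of n (remainder
dropped — sliding windows would bias set counts); per set, each
direction's scores are averaged and the argmax direction is the estimate
(6 classes, chance 1/6). Ties break by a seeded random preference order.
Grouping is per target *direction* rather than per block: with 30-trial
blocks and 5 folds, a per-block grouping would cap n at 6 and could never
produce the 10-trial averages the design calls for. Accuracy is reported
both pooled (correct sets / total sets) and as the unweighted mean of
per-fold accuracies.

Performance metrics, per SOA t and averaged-trial count n, with selection
duration c = n·N·t (N = 6 directions), reported per minute:

* BCI utility U = (2P/100 − 1)·log₂(N − 1)/c for P ≥ 50%, else 0 —
  accounting for error correction; below 50% accuracy corrections can
  never outpace errors.
* Wolpaw ITR = [log₂N + p·log₂p + (1−p)·log₂((1−p)/(N−1))]/c with
  p = P/100 and the 0·log 0 = 0 convention, clamped at 0.

Note the two do **not** coincide at P = 100 (log₂(N−1) vs log₂N); no such
equality is asserted anywhere.

## Problem sizes and verification

The package's own end-to-end checks use scaled simulations chosen to be
informative at desk scale:

* Chance-level recovery: one participant, SOA 0.5 s, all ERP amplitudes
  zero, 600 trials (24 blocks × 25) in the test suite and 2,400 trials
  (four 600-trial session chunks) in `scripts/acceptance.py`; single-trial
  accuracy must sit in the binomial 95% band around 16.7%.
* Target-interval check: 10,080 trials at 200-ms SOA; mean within-block
  target-to-target interval 1.2 s ± 2%.
* Closed-form-vs-numerical FDA agreement over 100 random instances
  (generalized-eigenvector maximization, 10⁴ random directions).
* BH-FDR against a brute-force step-up oracle on 10³ random vectors and a
  1,000-replicate null simulation (realized FDR ≤ q within two Monte-Carlo
  standard errors; under the full null BH attains q exactly).
* Qualitative SOA effect: 10 seeds × 3 participants × SOAs
  {0.2, 0.5, 1.1 s}, 6 blocks × 15 trials, PSO 6 × 8: mean accuracy
  non-decreasing in n (within two pooled binomial standard errors),
  ordered 200 ms < {500, 1,100 ms}, and utility peaking at 500 ms.

## Known limitations

* The simulator's linear Gaussian-bump model makes decoding easier than
  real EEG; absolute accuracies from synthetic cohorts are not comparable
  to human results and only orderings/chance levels are meaningful.
* Ocular-artifact handling is out of scope; recordings with artifacts
  should be cleaned before entering the pipeline.
* The per-SOA attenuation map is a stand-in for an unmeasured quantity.
* `read_events_tsv` infers the SOA from onset differences (median of
  within-block spacing); schedules with deliberately irregular spacing are
  not representable.
* Three-way ANOVA / post-hoc comparisons across SOA conditions are routine
  off-the-shelf statistics on the pipeline's output tables and are left to
  the user.
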