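# Methods

This note documents the models, estimators and numerical choices behind
`whiskpc`: what each analysis computes, what the synthetic-data generator
emulates (and what it does not), and where the design was genuinely open.

## Data model and conventions

Recording time is 0-based seconds. Trial windows are milliseconds relative
to stimulus onset; all intervals are half-open `[start, end)`. Whisker
angle is in degrees with protraction positive, so retraction minima are
negative. Spike trains carry simple-spike (SS) and complex-spike (CS)
times separately.

## Single-unit QC

A recording counts as a single Purkinje cell when it contains both spike
types, the minimal SS inter-spike interval is 3 ms, every CS is followed by
an SS-free pause of at least 8 ms, and the recording lasts at least 200 s.
Interval comparisons include a 1 µs guard so an interval of exactly 3.000 ms
never flips on floating-point rounding. An SS sharing a timestamp with a CS
is physiologically impossible and is reported as a distinct data error. The
8 ms pause rule is enforced strictly; the report carries a violation count
so that rare noise-spike contaminations remain diagnosable. Firing
regularity is summarized by CV2 = 2|ISIₙ₊₁ − ISIₙ|/(ISIₙ₊₁ + ISIₙ): 0 for
clock-like firing, expectation 1 for a Poisson train (the mean of
2|A − B|/(A + B) for iid exponentials), and the statistic is invariant to
time rescaling.

## PSTHs and the 3-s.d. criterion

Raw PSTHs hold, per 1 ms bin, the percentage of trials with at least one
spike. For quantification the raw PSTH is convolved with a unit-area
Gaussian kernel, truncated at ±4 s.d., with reflection padding — this
preserves total mass to better than 1e-9 relative and maps constants onto
themselves, avoiding spurious edge troughs. "Kernel width" is read as the
standard deviation (default 21 ms for response PSTHs, 8 ms for spike-density
functions); an `interpretation="fwhm"` switch covers the other common
reading of an "N ms Gaussian kernel".

Baseline statistics (mean, s.d. with ddof=1) are computed on the convolved
PSTH over −200..0 ms; the response is significant iff any convolved bin in
0..60 ms leaves mean ± 3 s.d. The peak is the earliest global extremum
among significant bins (ties break to the earliest bin — conservative for a
time-to-peak reading), reported as the PSTH value with its bin's left edge
as latency. If excursions exist in both directions the response is
biphasic, with up to two phases in temporal order. Degenerate baselines are
handled explicitly: a perfectly flat PSTH is not significant; a zero-s.d.
baseline with any response deviation is significant with an `infinite_z`
flag. An inter-trial window preset (−500..−200 ms) is exported for analyses
that need a baseline away from the preceding trial's tail.

Stability maps stack convolved SS PSTHs over blocks of 20 trials advanced
by 5, each row expressed as percent change from its own baseline mean over
−1000..−200 ms; row count is `floor((n_trials − 20)/5) + 1`.

## Responder clustering

CS response heterogeneity is essentially one-dimensional (the convolved
peak amplitude), so units are clustered with univariate Gaussian mixtures:
k ∈ {1,2,3} × {equal, unequal} variances, fitted by EM from 20 restarts
(an equal-count split of the sorted sample — the 1-D k-means fixed point —
plus random data-point draws; the mixture likelihood is genuinely
multimodal and 1-D EM is cheap). Convergence: relative log-likelihood
change < 1e-6, max 300 iterations; the per-iteration log-likelihood is
recorded and checked to be non-decreasing on every fit. A variance floor of
1e-6 × sample variance prevents singular components; all-identical data
forces k=1 with a flagged degenerate variance. Model selection uses
BIC = −2 ln L + p ln n with p counted per variance model (k−1 weights + k
means + k or 1 variances); lower is better. The strong/weak boundary solves
posterior equality between the two components of the winning k=2 model —
a quadratic in x, `(x−m₂)²/v₂ − (x−m₁)²/v₁ = 2 ln(w₂/w₁) + ln(v₂/v₁)` —
taking the root between the means; units above the boundary are "strong".
The test suite cross-checks log-likelihood, means and BIC against
scikit-learn's independent EM implementation.

## Trial-by-trial spike–whisker correlation

Spike density functions are per-trial 1 ms impulse trains convolved with an
8 ms Gaussian (reflection padding; an unaligned row integrates to its spike
count). Both SDFs and whisker epochs are aligned to the 200 ms pre-stimulus
baseline (per-trial mean subtraction). Each variable is reduced to 10 ms
bin means per trial over −100..+300 ms and every (spike bin, whisker bin)
pair is correlated across trials with Pearson's R, giving a 40 × 40 matrix.
Zero-variance bins produce NaN cells — never a silent 0 — and NaN cells are
excluded from the maximum search; ties break to the smallest (row, col).

**Sign convention.** Rows are spike-time bins and columns whisker-time
bins; the lag at the maximal cell is `whisker-bin time − spike-bin time`,
so a **positive lag means the simple spikes lead the whisker position**
(the spiking at time t correlates best with the angle at t + lag).

The diagonal (zero-lag) trace gets a 99% confidence band from 1000
trial-label permutations of the whisker epochs relative to the SDF trials —
a distribution-free null of no trial-by-trial coupling, consistent with the
resampling used elsewhere in the pipeline. Multi-cell pooling z-scores both
variables per cell per bin before concatenating trials, so duplicated cells
change nothing and opposite couplings cancel. The pre→post shift of the
maximal cell is reported as (Δrow, Δcol, Δlag), post minus pre.

## Whisker behavior and the adaptation bootstrap

Epochs default to −200..+500 ms with per-trial baseline subtraction
(idempotent by construction). Trial kinematics report the baseline angle,
the maximal retraction (minimum over 0..50 ms) and the maximal protraction
(maximum over 50..200 ms); the windows follow the reflex morphology (the
retraction peaks ~25 ms, the protraction ~80–120 ms after the puff) and are
configuration, not constants. Spontaneous whisking is a pre-stimulus
peak-to-peak amplitude above 10°.

Trials are sorted on the presence of a CS in the first 100 ms after onset;
the with-minus-without difference trace is summarized by its extremum. The
extremum is read off a copy smoothed with an 8 ms Gaussian (the SDF kernel):
the raw maximum over several hundred white-noise samples is biased upward
by ~0.3–0.4° at realistic noise, whereas the smoothed estimator recovers a
planted difference to ±0.05°. The CS lead is the difference-peak time minus
the convolved CS-PSTH peak time.

The adaptation test follows the published procedure exactly: the last 100
pre-induction trials are split at random (without replacement) into two
groups of 50, the difference of mean traces recorded, and the split
repeated 1000 times; the per-timepoint 99% percentile band of these
differences is the expected variability. The observed difference uses 50
randomly chosen post minus 50 randomly chosen pre trials — one draw by
default, with an `n_draw > 1` averaged variant clearly labelled as a
stabilized extension of the procedure. Inputs smaller than 2 × group size
(pre) or group size (post) are rejected, never silently shrunk; `n_boot <
100` degenerates the band and triggers a warning. Measured per-timepoint
type-I error is ~1.3–1.4% (slightly above the nominal 1% because the two
halves of a split are anti-correlated — a property of the procedure, not of
this implementation).

The pipeline's session-level "protraction increased" flag requires the
observed difference to exceed the band over a **sustained ≥ 10 ms run**
inside the protraction window: under the null, ~1% of timepoints exceed the
band by construction, so any-single-timepoint flagging would mark nearly
every unchanged session.

## Population coherence

Calcium transients report CS firing of individual PC dendrites. Detection:
subtract a rolling 8th-percentile baseline (0.5 s window — the natural
reading of the published parameters on ~25 Hz data), then matched-filter
with a peak-normalized double-exponential template (rise 10 ms, decay
150 ms; a stated phenomenological substitute for the original unpublished
template, fully configurable) and mark local maxima above
`threshold_k × MAD` of the filtered trace, with a minimum peak separation of
the template's post-peak e-folding time so one transient is never counted
twice. Limitation: when transients occupy more than about half the trace
(very high event rates), the MAD noise estimate is inflated and the
effective threshold rises; `threshold_k` is exposed for such data.

Events are binary per dendrite per 40 ms frame. Coherence is tested against
surrogate matrices drawn independently per dendrite per frame from a rate
model — by default the stimulus-aligned inhomogeneous rate (per-dendrite
mean at each post-stimulus lag, baseline elsewhere), preserving each
dendrite's rate modulation while destroying cross-dendrite coupling. The
Poisson rate is applied as a Bernoulli approximation with clipping at 1
(and a warning), since a dendrite cannot fire twice within one frame at
these rates; an analytic Poisson survival-function p is reported alongside
for comparison. Per simultaneity level m, p is the fraction of surrogates
whose frequency of m-coincidence frames reaches the observed frequency;
zero exceedances are reported as the upper bound 1/n_boot with a flag,
never as 0.

The overall distribution shift uses a two-sample KS statistic between the
observed per-frame counts and the pooled surrogate counts. Because the
counts are discrete, the asymptotic two-sample KS p is conservative under
ties, so the test also reports a surrogate-calibrated p: each surrogate is
scored with its own KS statistic against the pool of the remaining
surrogates (leave-one-out, treating surrogates and observation
symmetrically), and p is the fraction of surrogates at least as extreme.
With a correctly specified rate model this calibrated p rejects at the
nominal level; with a rate model estimated from the tested data itself the
procedure is conservative (the surrogates inherit the overfit rates), which
is the safe direction for a coherence claim.

## Synthetic sessions

The generator produces data with the study's structure and known planted
parameters; every effect the analyses report is recoverable by construction.

- **Protocol**: 100 puffs at 0.5 Hz, an 80-puff 4 Hz induction block, 100
  puffs at 0.5 Hz (30 ms puffs); deterministic onsets, phases contiguous.
- **Simple spikes**: inhomogeneous Poisson (baseline 65 Hz) thinned from
  the peak rate, with the planted biphasic response profile — gain 0.6 over
  2–30 ms, 1.6 over 30–100 ms after each puff (suppression then
  facilitation, per the typical recorded shape). A 3 ms absolute refractory
  period is imposed by sequential deletion, and every CS deletes SS within
  the following 10 ms, so generated units satisfy the QC rules by
  construction. `plasticity_gain` multiplies the response gains on
  post-induction trials.
- **Complex spikes**: 1 Hz homogeneous background plus, per trial with
  probability `cs_response_prob`, one stimulus-locked CS at latency
  N(20, 5²) ms.
- **Whisker trace** (1 kHz): per trial, a −5° retraction bump (peak 25 ms,
  s.d. 10 ms) plus a +10° protraction bump (peak 80 ms, s.d. 40 ms),
  amplitudes and widths chosen from the published reflex morphology;
  CS trials add `cs_trial_bonus` (default 0.8°, the scale of the recorded
  median difference) of extra protraction; the unit's own mean-centered SS
  density (8 ms kernel), lagged by `coupling_lag` (`post_coupling_lag` on
  post-induction trials), contributes `coupling_gain` degrees per spike/s;
  `post_gain` scales the protraction on post trials; white sensor noise
  s.d. 1.5°. The CS latency (20 ms) and protraction peak (80 ms) together
  plant a ~60 ms CS→protraction lead, the scale reported for the recorded
  population.
- **Event matrices**: independent Bernoulli baseline events everywhere
  (default 0.04/frame ≈ 1 Hz at 40 ms frames); on each stimulus frame, with
  probability `coherent_fraction` a single shared Bernoulli(evoked) draw
  fires all dendrites at once, otherwise each dendrite draws independently.
  Optional fluorescence synthesis convolves events with the transient
  template plus Gaussian noise.
- **Genotype presets** (`pipeline.GENOTYPE_PRESETS`): the `wt` arm plants
  `plasticity_gain = 1.3`, `post_gain = 1.18` (the published ~18%
  protraction increase) and a 0 → 20 ms pre→post coupling-lag shift (the
  published emergence of an SS lead); `ltp_deficient` plants no change
  anywhere. The 1.3 spiking gain is the smallest planted effect reliably
  detectable in a single 100-trial session at the pipeline's 99% confidence
  convention.

What the generator does **not** emulate: spontaneous whisking bouts and
slow behavioral state drift (noise is white), video-tracking artifacts,
waveform-level spiking (no spikelets, no amplitude modulation), latency
drift within a session, dendrite-to-dendrite rate heterogeneity beyond the
sampled parameters, and neuropil/motion contamination of fluorescence.
Passing tests therefore demonstrate that the estimators recover planted
effects under the study's nominal structure and noise scale — not that they
are robust to every artifact of real recordings.

Randomness: one seeded generator per session with per-component substreams
(`numpy` `spawn`); identical seeds give identical outputs, and every
pipeline run is reproducible bit for bit from its config.

## Statistical conventions in the pipeline

Session-level significance follows a 99% confidence convention throughout:
the bootstrap band at 99%, the permutation CI at 99%, and the pre/post SS
count comparison (Mann-Whitney on per-trial counts in 0–60 ms) at
α = 0.01. The responder fraction helper samples CS response probabilities
from a three-class mixture (≈10% non-, 56% weak, 34% strong responders)
chosen to emulate the recorded population's composition.

## Problem sizes

Simulation-based checks use: 10⁵ intervals for the CV2 expectation; 100
seeded datasets of n = 132 (66 + 66, separation 4 s.d.) for GMM selection;
500 null sessions (100 pre + 50 post trials) for bootstrap calibration and
100 for power; 100 sessions of 100 trials for lag recovery; 200 trials for
the CS-sorted comparison; 8 dendrites × 1000 frames with 200 null repeats
(200 surrogates each) and 100 planted-coherence repeats (500 surrogates)
for the coherence test; and one full 280-trial session per genotype arm for
the end-to-end contrast. These sizes keep any single check within seconds
to a couple of minutes on one core while leaving Monte-Carlo error well
inside the asserted tolerances.
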