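# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `optoephys`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Kinematics

**Rotational speed and immobility.** The per-sample rotational speed is the
Euclidean norm of the 3-axis angular velocity (deg/s).  Immobility segments
are maximal runs *strictly* below 20 deg/s lasting at least 1 s; samples
exactly at the threshold break a run.  The same strictness applies to the
10 deg/s trial-inclusion rule of the resultant vector (a trial at exactly
10 deg/s is excluded) and to the rest/active trial split, which inspects
the half-open second [onset − 1 s, onset).

**Peak rotations.** The *during* search window is the stimulation interval
itself; the *post* window is 0–600 ms after offset, covering the ~200 ms
latencies typical of offset-evoked rotations with margin.  Both are
configurable.  Trials whose window leaves the recording are dropped with a
logged warning, never padded.  An all-zero gyro window yields peak speed 0
with a flagged, undefined axis.

**Resultant vector and its null.** The resultant is the mean of per-trial
unit axes over qualifying trials; its length is in [0, 1] and equals 1 iff
all axes coincide.  The null table holds, for every N in 1…100, the mean
and 2.5th/97.5th percentiles of the resultant length of N uniformly random
unit 3-vectors, from 10 000 Monte-Carlo samples.  The implementation draws
one (samples × N × 3) Gaussian block, normalizes, and uses cumulative sums
across N (common random numbers), which makes the empirical mean curve
monotone non-increasing at this sample size and is O(1) per additional N.
Closed forms pin the curve at both ends: mean 1 at N = 1 exactly, 2/3 at
N = 2, and ~N^(−1/2) decay at large N.  A session with N outside the table
raises; callers regenerate the null with a larger Nmax rather than
extrapolate.  The 0.4 "good alignment" reporting filter is exposed as a
constant (`GOOD_ALIGNMENT_LENGTH`) and is not part of the bias test.

**Gravity and orientation.** Gravity is the normalized mean acceleration
over immobility samples; the orientation of a rotation axis is its 3-D
angle to that vector (arccos of the signed dot product).  No quaternion
attitude tracking is attempted, and no 2-D quadrant projection is reported:
only the 3-D angle to vertical.  The ipsi/contraversive sign convention
follows the right-hand rule in the sensor frame; mapping to anatomical side
depends on sensor mounting and is left to the caller's configuration.

## Spike trains

**Rates and ISI statistics.** The firing-rate denominator is the recording
span, not first-to-last spike, so sparse units are not inflated.  ISI CV
needs ≥ 3 spikes, the median ISI ≥ 2; below that the fields are NaN and
flagged.  Log transforms are natural logs; in the pipeline, zero rates are
floored at 0.01 Hz before the log (config constant).

**Burst detection.** Bursts are scored by the Legendy–Salcman Poisson
surprise S = −ln P(≥ n spikes in T | Poisson at the train's mean rate),
with P evaluated through the exact Poisson survival function in log space.
Seeds are runs of ≥ 2 consecutive ISIs below half the mean ISI (≥ 3
spikes); each seed is greedily extended forward with a 10-spike look-ahead
and then trimmed at its start, keeping any step that increases S; bursts
with S ≥ 10 are kept and overlapping bursts merged.  The surprise cutoff,
minimum spike count and look-ahead are parameters; the defaults are
declared choices, not inferred from data.  The unit tests verify every
reported surprise against an independent exact-tail summation (lgamma +
log-sum-exp) to 1e-9.

**Waveforms and sorting.** Extraction uses negative-going threshold
crossings with 1 ms refractory censoring and trough alignment within
0.3 ms; a threshold inside ~3 robust noise SDs triggers a warning with the
crossing rate.  Sorting is PCA (3 components) followed by seeded k-means
(10 restarts); k comes from the caller or the max silhouette over 2–5.
Narrow vs broad waveforms split at 0.35 ms trough-to-peak (strict <;
boundary = broad); a waveform whose trough is its last sample is
unclassifiable.  Complex-spike labels pass through from the generator or
input files — automatic complex-spike detection is out of scope.

## ECoG

**Morlet transform.** A bank of complex Morlet kernels with n = 7 cycles
(σ_t = n/2πf), truncated at ±3σ_t and normalized so a sustained
unit-amplitude sinusoid at f yields coefficient magnitude 1 at f.  This
makes the reported peak amplitude a µV-equivalent of a sustained
oscillation; absolute comparison with other normalizations is out of
scope.  The frequency grid steps 1 Hz through the band.  The analysed
window is epoched with a ±3-wavelet-width margin at the lowest band
frequency and cropped after the transform, so the window is free of edge
artifacts.  Peaks landing on the window or band edge are returned but
flagged `at_boundary`; a flat map returns amplitude 0 flagged `degenerate`.

**Peak extraction.** The readout is the argmax of coefficient magnitude in
band × window; defaults 15–40 Hz and 0–100 ms after stimulation offset.
The identical machinery with band (2, 15) Hz and a longer window implements
the low-frequency (waves > 100 ms) variant with no code change.  Window
bounds are always explicit parameters.

**Evoked-wave model in the generator.** The synthetic evoked wave is a
Gaussian-envelope oscillatory packet centred at offset + latency (default
σ = 40 ms).  A one-sided exponentially damped cosine was considered and
rejected: convolving its envelope with the wavelet's Gaussian gives an
ex-Gaussian whose mode lags the wave onset by ~20–25 ms at these
bandwidths, so "injected latency" would not be the time of the largest
oscillation — which is what the TF peak measures.  With the symmetric
packet the injected latency *is* the envelope maximum, and the recovery
tests meet ±2 Hz / ±15 ms across the 16–38 Hz sweep.  The envelope σ
default (40 ms) keeps the packet's spectral width (~4 Hz) well inside the
wavelet bandwidth; much shorter packets bias the recovered frequency
upward by ~σ_packet²/f because the unit-sinusoid normalization gives the
bank a gain ∝ f.

**Background.** 1/f^α noise (α = 1 default, flattened below 1 Hz) scaled
to 50 µV RMS.  No noise model is prescribed by the protocol; both α and
the RMS are free `SimConfig`-level parameters.

## Behavior

The elongation statistic is the standard second-central-moment
eccentricity E = 100·√((Sxx−Syy)²+4Sxy²)/(Sxx+Syy) with uniform point
weighting; it is similarity-invariant and satisfies the anchors 0 (circle),
100 (line) and 60% for an aspect-ratio-2 ellipse sampled uniformly in
parameter angle.  Whether commercial trackers weight contour points by arc
length instead is unknown; uniform weighting is the declared choice.
Posture thresholds are strict (> 70 stretched, < 50 contracted; boundaries
are "normal").  Video inactivity uses a *precomputed* frame-change percent
series (strictly below 0.8%); the pixel signal is not reconstructable from
a trajectory, so the generator emits one coupled to trajectory pauses
(≈2% moving, ≈0.3% paused).  The movement-bout floor for bout velocity is
0.5 cm/s (declared, the bout definition being otherwise unspecified).

## Synthetic-data generator

The generator's defaults are the study conditions: 1 s stimulation at
0.25 Hz, 200 Hz IMU (5 ms resolution), 1 kHz ECoG, 25 kHz raw traces,
38 cm circular arena, 5 min open-field sessions.  Units are fixed: s, Hz,
deg/s, µV, cm, g.

- Spike trains are gamma renewal processes (order 1 = Poisson; order ~4
  for tonic units); Purkinje "normal" mixes ~55 Hz simple with ~1 Hz
  complex spikes, "slow" gates 8 Hz firing through alternating up
  (mean 1.5 s) / down (mean 3 s) states to land under 10 Hz, and
  "cs_only" keeps ~1 Hz complex spikes.
- Rotation-event axes are von Mises–Fisher draws (scipy) around the mean
  axis; κ = 0 is isotropic, κ ≥ 1e6 collapses to the mean axis exactly.
  The speed bump is a Gaussian profile (σ = 50 ms default) added along the
  drawn axis; baseline gyro noise is white, scaled so the resting speed is
  ~5 deg/s — a simplification (real gyro baselines are band-limited) that
  the immobility and classification logic does not depend on.
- Gravity is a constant 1 g vector (default −z) plus 0.02 g white noise;
  this supports orientation-vs-vertical tests without attitude simulation.
- Trajectories are correlated random walks (heading diffusion 0.4 rad/step,
  gamma speed jitter) with a two-state pause Markov chain whose stationary
  pause probability is the `pause_prob` argument, reflected at the wall.
- Raw traces insert three biphasic templates (troughs ~80–120 µV, distinct
  widths/peaks) at Poisson times with 1 ms refractory; SNR 10 in the tests
  means 10 µV noise SD against the ~100 µV mean trough.

What the generator does **not** emulate: sensor drift and calibration
error, movement artifacts in ECoG, electrode drift and overlapping-spike
waveform superposition beyond linear addition, arena-wall behavior
(thigmotaxis), or any lesion biophysics — group differences are injected
parametrically.  Passing tests therefore demonstrate correctness of the
analysis code under the stated statistical models, not robustness to every
artifact of real recordings.

## Pipeline and statistics

`run_experiment` is a pure function of `ExperimentConfig`: a root
`SeedSequence` spawns one stream per animal and stage, so re-runs are
byte-identical.  The default two-group conditions use the week-3 study
values: M1 0.96 vs 0.47 Hz, cerebellar nuclei 9.6 vs 19.3 Hz, Purkinje
slow-cell fraction 1/15 vs 1/2, ECoG wave 40 vs 20 µV (the 0.80:0.39
amplitude ratio; absolute µV depends on wavelet normalization, so the
synthetic amplitudes are set against the 50 µV background to be
recoverable from ~29 trials), wave latency 40 vs 58 ms, open-field speed
9.2 vs 7.1 cm/s, immobility 50% vs 78%, 5 + 5 animals, 120 s
electrophysiology sessions, 20 units per region per animal, with
lognormal unit-level (CV 0.3) and animal-level (CV 0.1) rate variability.
These sizes keep a full two-group run near ten seconds while leaving the
group contrasts detectable.

The χ² test is Pearson without continuity correction — required to
reproduce the worked 2×2 example (χ² = 7.06) — and refuses tables with a
zero marginal.  The KS test reports the asymptotic p.  "Repeated-measure"
ANOVA is approximated by aggregating units to per-animal means and
computing a one-way F across animals (mouse as the repeated unit).  This
is deliberately simpler than a mixed-effects model: it is exactly
invariant to per-animal unit-count imbalance and its direction/size
behavior is testable by simulation, but it does not partition within- vs
between-animal variance and is *not* asserted equivalent to a
random-factor ANOVA.  No multiple-testing correction is applied; raw
p-values are reported.

## Known limitations

- Amplitude units of the TF peak are tied to this package's wavelet
  normalization; cross-study amplitude comparison is out of scope.
- The burst detector's greedy extension maximizes surprise locally; it is
  not guaranteed to find the global-maximum-surprise partition (no
  standard definition does).
- The alignment test's false-positive rate is nominal (5%) only under the
  isotropic null; correlated trial axes within a session would inflate it.
- No drift correction or cross-session unit tracking.
- CLI plotting is intentionally absent; the CSV outputs are designed for
  downstream plotting tools.
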