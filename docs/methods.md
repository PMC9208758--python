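# Methods

`munit_task` re-implements, as a tested offline pipeline, the
computational core of a single-motor-unit biofeedback experiment: a
buffered spike-rate-to-cursor task engine, ramp-based recruitment /
de-recruitment threshold estimation, trial-level performance analyses,
and two-source decomposition validation — exercised end-to-end on a
synthetic motoneuron-pool generator.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
world does and does not establish.

## The motoneuron-pool model

A pool of `n_units` motor units (MUs) shares one scalar drive `I(t)`
expressed in %MVC-equivalent units (the common-input abstraction: under a
shared drive, recruitment is fixed by per-unit thresholds — Henneman's
size principle).

Per unit:

* **Recruitment threshold** `theta_on` (%MVC), drawn uniformly in
  `threshold_range` (default 1–9 %MVC, inside the 10 %MVC ramp range) and
  sorted ascending.
* **De-recruitment threshold** `theta_off = theta_on + N(-1.11, 2.44)`
  %MVC, clipped at a 0.05 %MVC floor.  The defaults restate the reported
  population hysteresis (mean offset 1.11 %MVC below onset, SD 2.44, so
  ~67.5% of units de-recruit below their recruitment threshold and the
  rest above).  Clipping rather than re-drawing keeps the reversal
  fraction exactly at the normal-CDF value for every threshold.
* **Rate coding**: while active, the instantaneous rate is
  `min(r_sat, r_min + rate_gain * max(0, I - theta_on))` pps — linear
  above threshold with a hard saturation, floored at the recruitment rate
  `r_min`.  Defaults (`r_min` 7–9 pps, `rate_gain` 0.3–0.6 pps per %MVC,
  `r_sat = r_min + 3–5` pps) give plateau rates of ~9–13 pps at 10 %MVC,
  typical of low-threshold tibialis anterior units.
* **Discharge variability**: spikes are a renewal process with ISI mean
  `1/rate` and coefficient of variation `isi_cov` (default 0.1,
  physiological for steady contractions).  The ISI perturbation is
  Gaussian with a lower clip at 20% of the mean (prevents non-physical
  near-zero intervals; for `isi_cov <= ~0.3` the realised CoV is
  essentially the nominal one).  The first spike of every activation
  epoch falls at the activation instant, so recruitment times are exact.

### Activation state machine

The de-recruitment threshold may sit above or below the recruitment
threshold, and both signs must be expressible (the estimation pipeline is
expected to recover them).  A naive level-triggered rule
(activate when `I >= theta_on`, deactivate when `I < theta_off`) cannot
do this: whenever `theta_off > theta_on` it either chatters at the sample
rate or collapses de-recruitment onto `theta_on`.  The engine therefore
uses an *armed crossing* machine:

* a unit activates at an upward crossing of `theta_on`;
* while active, its de-recruitment level is `theta_off` once the drive
  has reached `theta_off` since activation ("armed" — immediate whenever
  `theta_off <= theta_on`), and `theta_on` otherwise;
* after de-recruitment, re-activation again requires an upward crossing
  of `theta_on`.

A unit whose elevated de-recruitment threshold is never reached by the
drive simply de-recruits at its recruitment threshold — the hysteresis is
latent, exactly as it would be unmeasurable in a ramp that never reaches
it.  One structural consequence holds for *every* drive trajectory: any
path from rest to the higher recruitment threshold first crosses the
lower one, so the lower-threshold unit always fires before (and while)
the higher-threshold unit is first recruited.  Direct TIII movements
(sole activation of MU2 from rest) are therefore impossible in this
deterministic world; the real, rare direct movements are attributed to
recruitment-order variability under synaptic noise, which the generator
deliberately omits.

### Force and EMG stand-ins

* Force = drive + zero-mean noise low-passed below 5 Hz (4th-order
  Butterworth, forward-backward), rescaled to `force_noise_sd` and
  mean-removed exactly.  No twitch convolution: the analyses consume only
  100 ms window averages, which a twitch model would not change
  materially.
* The "global EMG" is a zero-mean white carrier amplitude-modulated by
  the summed pool rate plus additive noise — sufficient for envelope
  (rectify + 10 Hz low-pass) analyses, monotone in pool activity by
  construction.
* A separate waveform-bearing generator places a fixed biphasic
  multichannel waveform at every discharge; it supports spike-triggered
  averaging and waveform-correlation matching but is deliberately *not*
  a mixing model adequate for testing blind-source separation.

## Ramp analysis

* **Onset**: first spike that starts a run of >= 2 discharges with ISI
  <= 200 ms (the "5 pps or above" rule read as instantaneous rate; robust
  to isolated spurious spikes).  **Offset**: last spike followed by >= 1.5 s
  of silence, taking the final activation episode of the analysis
  interval; the gap to the interval end counts.
* Threshold forces are means over closed, sample-inclusive 100 ms windows
  centred on the events.  With the deterministic generator
  (`isi_cov = 0`, noiseless force, 1 %MVC/s ramp) the recovered
  thresholds sit within ~`slope / r_min` (<= 0.17 %MVC) of the truth —
  the residual is the sub-ISI delay between the last spike and the true
  de-recruitment instant.
* Units are ranked by ascending onset force (ties: earlier onset, then
  unit id).  Reference rates are plateau spike counts divided by plateau
  duration.
* Pair selection splits the ranked pool into first/last recruited halves
  (odd pool: extra unit to the first half) and picks one adjacent-rank
  pair per half, with a seeded random choice weighted by `1/(df_on + 0.1)`
  toward the smallest within-pair threshold difference.  Condition III
  pools MU1 of the low pair with MU2 of the high pair.
* The envelope operator uses zero-phase filtering (no group delay under
  the 100 ms reads); a causal online implementation would lag — an
  explicit deviation from any real-time system.

## Cursor engine

Buffers are 256 samples at 2048 Hz (125 ms).  Per axis: trailing
8-buffer (1 s) mean of the per-buffer spike rate, divided by the unit's
reference rate at 10 %MVC and multiplied by a gain, then a trailing
6-buffer (750 ms) moving average — a cascade with exactly 13 buffers
(1625 ms) of support.  Both windows include the current buffer; that is
what makes the stated 1 s / 750 ms / 1625 ms arithmetic hold.  At stream
start the windows shrink to the available buffers (no zero padding, so a
constant input produces no artificial dip); a step preceded by silence
reaches its asymptote exactly at the 13th buffer.  Spikes on buffer
boundaries belong to the later buffer.  Normalised rates are not clamped.

Targets TI=(1,0), TII=(1,1), TIII=(0,1) have radius 0.1; each angle wedge
is the unbounded cone from the origin tangent to the target circle
(half-angle `arcsin(radius/||center||)`), cropped by the inner 0.4
circle; the far side of the displayed triangle is not modelled.  Regions
are closed; the target disc is tested first and counts as inside its
wedge; the origin belongs to neither region.  A target hit requires 7
consecutive in-target buffers (875 ms) and ends the trial; an angle hit 7
consecutive in-wedge buffers (trial continues); a trial times out after
160 buffers (20 s); 2 s of rest at the origin precede every onset.

Closed-loop sessions drive the pool with idealised per-target policies:
constant-level drives whose steady normalised rates are closest to the
target centre (TI, TII), and for TIII a three-stage profile — rise above
MU2's recruitment threshold, a brief dip into the interval between the
pair's de-recruitment thresholds to silence MU1 (possible only when the
de-recruitment order is reversed), then a slightly raised hold until the
hit.  The stage-2 dip is brief and the stage-3 hold long, matching the
described strategy ("reduce to a minimum, then slightly increase
again"); consequently the characteristic forces order as f1 > f3 > f2.
Session gains default to a familiarisation-style calibration (each
unit's attainable steady rate in its target regime maps to normalised
rate 1); the study's reported average gains (1.15/1.16) can be passed
explicitly instead.

## Trial metrics

* Performance: summand `(d/dmax)^2 + (phi/phimax)^2` per buffer, summed
  over the trial; `dmax = sqrt(2)` and `phi_max = 90 deg` for TI/TIII,
  `dmax = ||TII||` and `45 deg` for TII; `phi := phi_max` at the origin
  (absolute angle; no sign convention is imposed).  Normalisation
  `(worst - raw)/(worst - best)` is clipped to [0, 1].  The worst bound
  is the origin-hold closed form (240.0 for TI/TIII, 320.0 for TII at
  160 buffers); the best bound is simulated through the engine itself.
  A `variant="rss"` switch takes the per-buffer square root, since the
  printed formula is typographically ambiguous; the default is the
  literal sum of squares.
* Nearest miss and unintended hits are exhaustive window/excursion scans
  (verified against brute-force oracles); re-entries count separately,
  so unintended rates can exceed 100%.
* Direct movements use the strict any-spike rule (zero discharges of the
  other unit from target onset to the qualifying hit), whereas the
  stage-force epochs use the >5 pps trailing-rate criterion; both
  thresholds are arguments.

## Two-source validation

Greedy chronological one-to-one discharge matching within 1 ms; on trains
whose ISIs exceed 2 ms (always, physiologically) it equals the optimal
bipartite matching, which the tests verify via an assignment solver.
RoA = 100 * common / (common + A-only + B-only) — the standard two-source
denominator.  Per-phase RoA assigns matched pairs by their source-A time.
Under the controlled corruption model (independent deletions `p_miss`,
uniform insertions at rate `p_extra`, jitter << tolerance) the expected
RoA is `100 (1 - p_miss) / (1 + p_extra)`.  STA windows default to
±25 ms; unit pairing correlates channel-concatenated, mean-removed
waveforms and resolves candidates above 0.9 greedily by descending
correlation.

## What a green test establishes — and what it does not

The generator emulates *reported statistics* of a human experiment (pool
size, threshold ranges, hysteresis distribution, ramp protocol); it is
not a biophysical model and was never fitted to subject data.  Hit rates
and performance values from the idealised closed-loop controller are
properties of this stated world, not reproductions of human learning
curves; human headline numbers (hit rates, performance trajectories,
real-EMG agreement rates) are out of reach by construction.  What the
suite does establish: the engine's timing arithmetic, the geometry and
hit rules, the metric's closed forms and endpoints, threshold recovery on
noiseless ramps (within 0.2 %MVC for every threshold the ramp can reach —
de-recruitment thresholds at or above the 10 %MVC plateau are physically
unmeasurable by the protocol and excluded), the impossibility of direct
TIII movements under deterministic common drive, and the RoA closed form.

## Numerical choices

* All randomness flows from `numpy.random.default_rng` seeded per
  operation call; sessions spawn per-trial child seeds below 2^31.
* Heavy simulations sample the drive at 512 Hz instead of 2048 Hz where
  only spike times and 100 ms force averages are consumed; the engine's
  buffer arithmetic is independent of the drive grid.
* Window reads use closed intervals with half-sample tolerances; region
  tests use 1e-12 boundary tolerances; the deterministic renewal loop
  tolerates 1e-9 s at epoch ends so exact-rate fixtures include the
  boundary spike.
* The statistics wrappers delegate to `scipy.stats` (Wilcoxon with
  `zsplit` zeros handling, Friedman, Spearman).  The original study's
  linear mixed model is replaced by a paired Wilcoxon on per-session mean
  differences, labelled as a substitute.

## Known limitations

* No synaptic noise, so recruitment order is strictly deterministic and
  direct TIII movements never occur (the experiment observed rare ones).
* Static per-unit `theta_off`: history-dependent excitability (persistent
  inward currents) is abstracted into a single reversal-capable offset;
  no activity- or time-dependence.
* The EMG stand-ins support envelope and averaging analyses only; no
  decomposition is performed anywhere (out of scope).
* The ramp-failure criterion of the original protocol (force-tracking
  quality) is not modelled; the generator always "follows" the ramp.
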