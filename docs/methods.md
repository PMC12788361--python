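# Methods

This note documents the models, defaults and design choices behind
`slidegait`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Signals and units

Per limb, five synchronized 100 Hz channels: hip flexion, hip abduction,
knee flexion, ankle dorsiflexion (degrees; negative abduction =
adduction, negative dorsiflexion = plantarflexion) and total plantar
pressure (newtons, aggregated over the insole). A gait cycle runs from
pressure onset (first board contact) to pressure disappearance (end of
push-off) and contains four phases: initial loading ramp, double-leg
support gliding (pressure plateau), single-leg support (first pressure
peak), push-off (maximal peak, then unloading to zero).

## Synthetic cycle generator

The generator reproduces *signal statistics*, not rigid-body physics.
Each phase holds per-channel knot sequences (fraction-of-phase, value);
trajectories are monotone cubic (PCHIP) interpolations through the knots,
built piecewise per phase so slope discontinuities at phase boundaries
are preserved — this is what makes the boundary features detectable to
sample precision. Knot times are snapped to the sample grid so zero-noise
channel extrema equal the configured targets exactly.

Default amplitudes are calibrated to published phase-wise values of an
elite-youth slideboard session: initial-phase hip/knee/ankle flexion
108.7/95.8/23.1° left and 115.6/95.5/23.7° right, hip abduction −2.4°
left / 12.3° right; double-support pressure bands 90–148 N (left) and
140–193 N (right); first pressure peaks 251.9/313.4 N; push-off peaks
298.9/332.0 N; terminal abduction 51.0/53.3°. Cycle durations are not
published, so defaults are 3.25 s (left) and 3.24 s (right), i.e. 326/325
samples matching the published per-side sample counts, divided into four
equal-duration phases. Interior pressure knots on the steep segments are
spaced for near-uniform slope: this caps the cycle's peak |dF/dt| so that
the relative plateau threshold (10 % of peak slope) falls *below* the
initial loading-ramp slope and *above* the plateau slope — generator and
segmenter are consistent by construction.

Noise is i.i.d. Gaussian per channel, default SD 1.0° (angles) and 2.0 N
(pressure), consistent with the sensors' stated dynamic accuracy (±2°
IMU; the generator's 1° default is the mid-range between static ±1° and
dynamic ±2°). No drift term is simulated, since zero-bias calibration at
acquisition removes drift in the instrument chain being emulated.
Pressure is clipped at 0 N and pinned to exactly 0 at the first and last
cycle samples. An optional coupling mode replaces the pressure channel by
a cubic polynomial in one standardized joint angle plus noise (shifted to
a nonnegative range), giving a known ground-truth coefficient set for
regression-recovery tests.

What passing tests on these cycles do **not** show: robustness to drift,
dropout, soft-tissue artifact, multi-cycle fatigue trends, or per-region
insole maps — none of which the generator emulates.

## Kalman filter

One 10-state constant-velocity filter per limb (a single bilateral
20-state filter would add no coupling, as the model has no cross terms).
Forward pass only; covariance updates use the Joseph form with explicit
symmetrization, and P stays PSD to machine tolerance. The measurement
model's noise is N(0, R); R defaults to (2°)² per angle channel (dynamic
instrument accuracy) and (2 N)² for pressure.

Process noise is diagonal: position entries 1e-4, velocity entries 25
(deg/s)²/step for angles and 2500 (N/s)²/step for pressure. The velocity
entries are sized from the calibrated cycle's acceleration scale (knee
sweeps ~65° in 0.8 s, pressure ~300 N in under a second, i.e. per-step
velocity changes of a few deg/s and tens of N/s): smaller values (e.g.
0.1) visibly lag the fast transients and *increase* truth-referenced MSE
on synthetic cycles, so the defaults are chosen to denoise every channel
(smoothed/raw MSE ratios ≈ 0.2–0.6 at default noise). All entries are
configurable per channel.

Degenerate Δt = 0 is accepted (A collapses to the identity) as a
well-defined limit; negative Δt is a configuration error. Missing or
non-finite samples are rejected, never imputed.

## Segmentation

All thresholds are relative, so segmentation is invariant to uniform
pressure rescaling:

* onset: max(5 N, 2 % of the cycle peak), with a 5-sample hysteresis
  hold on both the rise and the fall;
* b1: first run of |dF/dt| below 10 % of the cycle's peak |dF/dt|
  sustained ≥ 0.15 s (the plateau); dF/dt comes from the filter's
  velocity state when available, else central differences, and is passed
  through a 9-sample centered median filter — an odd-window median leaves
  a clean slope step exactly in place (noiseless boundary error 0–1
  samples) while preventing noise spikes from fragmenting the plateau
  run;
* b2: first local pressure peak after the plateau with prominence ≥ 10 %
  of the cycle peak; if the only prominent peak is the global maximum, b2
  falls back to the preceding local minimum;
* b3: last local pressure minimum (the pre-push-off trough) before the
  global maximum; push-off therefore always contains the global peak.

Joint-angle confirmations (hip-abduction minimum inside single support;
maximal knee-extension rate inside push-off) are advisory: they are
reported per boundary but never veto the pressure features, because the
hard arbiter used in practice (motion video) is out of scope. On noisy
cycles boundary error grows smoothly with noise SD; on noiseless default
cycles all three boundaries are recovered within ±1 sample.

## Metrics and symmetry

Descriptive statistics use the sample SD (n−1); CV = SD/|mean| and is
flagged undefined at zero mean. The symmetry index is
SI% = |L − R| / (|L + R|/2) × 100 — this exact form reproduces all the
published SI values derivable from the published summary table (10.46 %,
26.70 %, 1.22 %, 0.34–3.46 %, 0 %). When the sides have strictly opposite
signs the percent form is structurally meaningless and the absolute
difference in native units is reported instead (8.93° for the ankle
minima −5.04° vs 3.89°). Timing metrics are compared as
cycle-normalized fractions so unequal cycle lengths remain comparable.
Report rounding is 2 decimals, half-up.

The paired Wilcoxon signed-rank test drops zero differences, uses an
exact two-sided p (dynamic programming over the signed-rank-sum
distribution; verified against full 2^n enumeration for n ≤ 12) when
n ≤ 25 without ties, and the normal approximation with tie and
continuity correction otherwise. Z is reported in both branches, signed
so that Z > 0 means the right side tends to exceed the left.

## Coupling regression

Both variables are z-scored over the analyzed cycle; powers are formed
from the standardized angle and **not** re-standardized, which forces
B(X₁) = Beta(X₁) exactly while higher-order B and Beta differ — matching
the reporting convention of the source tables. The raw (non-orthogonal)
polynomial basis is deliberate: the per-term t tests are marginal tests
on correlated powers; the design's condition number is recorded and a
warning is raised above 1e6. Degrees of freedom for t and the 90 % CI are
n − 4. Standardized residuals are scaled by √(RSS/(n−4)); an exact fit
(RSS at rounding level) is flagged degenerate rather than divided by a
near-zero scale. Within-cycle samples are serially dependent; plain OLS
inference is reported with the lag-1 residual autocorrelation attached as
a diagnostic, not replaced by a corrected estimator.

A note on recovery testing: because the response is standardized by its
sample SD, confidence intervals cover the *generative* coefficients
exactly at nominal level only after mapping back to the generative
response scale (multiplying the CI by sd(y); OLS is equivariant under
this affine map). Coverage measured this way over 500 synthetic
replicates at n = 325 is 88–89 % for all three terms at the 90 % level.
Coverage of a fixed standardized-scale truth would over-cover the
first-order term (~98 %), because the sample-SD rescaling correlates
with the estimate.

## Pipeline

All randomness flows from one config seed; per-cycle streams are spawned
via seed sequences. Outputs are written with fixed float formatting, so
identical config + seed reruns are byte-identical; the run manifest
records a hash of the analysis config (excluding run location), the seed
and library versions. For multi-burst file inputs the middle complete
burst is analyzed by default (the steady-state cycle), overridable by
index. Repeatability across repeated cycles is summarized per metric by
the across-cycle CV and the maximum pairwise difference; identical
cycles report exactly zero spread.

## Problem sizes used in tests

Simulation-based checks run at the sizes that make their statistics
stable while staying lightweight: 50 seeded cycles for the denoising
comparison, 20 seeds × 1000 samples for innovation whiteness, 500
Monte-Carlo replicates at n = 325 for CI coverage, and full 2^n
enumeration up to n = 12 for the Wilcoxon oracle.

## Known limitations

* The generator's trajectory shapes between the calibrated endpoint
  targets are a modeling choice (monotone cubic); real cycles have richer
  within-phase structure.
* Per-region (multi-cell) insole pressure maps, center-of-pressure
  trajectories, and video-based verification are out of scope.
* The Kalman model is kinematically uncoupled across channels; it smooths
  jointly but does not exploit inter-joint correlations.
* OLS p-values and CIs ignore within-cycle serial dependence (reported,
  not corrected), as in the analysis convention this package follows.
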