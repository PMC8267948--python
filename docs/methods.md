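# Methods

This note documents the models and numerical choices behind `atriamap`: what the
synthetic tissue generator simulates, how each electrophysiological metric is
computed, which conventions were fixed where several were defensible, and what
the validation suite does and does not establish about real recordings.

## Geometry

The recording array is modelled as 25 bipolar channels on a regular 5×5 grid at
0.5 mm pitch (a 6×6 unipolar plaque yields 25 bipoles, each placed at the
centroid of a unipolar pair; 25 = 5×5 makes all quadruplet and triangle
constructions regular). Positions are in mm with x along columns and y along
rows; channel names are `r{row}c{col}`, 1-based in files, 0-based in memory.
Times are ms, voltages mV throughout; conduction speeds are reported in m/s,
numerically identical to mm/ms, so no unit conversion appears anywhere.

The simulated tissue extends 0.8 mm beyond the electrode footprint on every
side (a multiple of the 0.1 mm simulation lattice, so electrodes sit exactly on
lattice nodes). Pacing corners are the two diagonal tissue corners (LAA at the
origin corner, LAFW opposite). The margin guarantees that even the nearest
electrode activates after the 2 ms post-stimulus blanking at the fastest preset
speed; without it the stimulus-corner channel would be unannotatable.

## Synthetic tissue

**Speed field.** White Gaussian noise on the fine lattice is smoothed with a
Gaussian kernel (correlation length 0.4 mm by default), renormalized to unit
sample variance, and exponentiated to a log-normal field with commanded
coefficient of variation `velocity_cv_frac`; a final rescaling makes the sample
mean equal the commanded mean speed exactly. `velocity_cv_frac = 0` produces a
constant field and consumes no random numbers, so the zero-heterogeneity case
is seed-independent by construction.

**Propagation.** Activation times are shortest-path travel times on the
8-connected lattice, with per-edge time = edge length × mean of the endpoint
slownesses (equivalently, length divided by the harmonic mean of the endpoint
speeds). On constant fields this is exact along lattice axes and diagonals and
overestimates oblique directions by at most sec(22.5°) − 1 ≈ 8.3% (the octile
bound); refining the lattice on a fixed heterogeneous field converges
monotonically. This discretization, not detection error, is why measured mean
CV on corner-paced constant tissue sits ~3–4% below the commanded speed; planar
waves (generated analytically) have no such bias. Heterogeneous substrates add
a small upward "fast-path" bias, since arrival times are governed by the fastest
routes. A PDE eikonal solver would remove the octile bias at the cost of a much
heavier dependency; the lattice model was chosen because it has a provable
closed form in the homogeneous limit, which the tests exercise directly.

**Electrograms.** Each captured stimulus adds, per channel, one symmetric
biphasic deflection (difference of Gaussians, narrow lobe σ = 0.8 ms, width
~4 ms, default amplitude 1 mV) centred at the continuous arrival time, plus
i.i.d. Gaussian noise (default 0.05 mV for presets). The deflection's maximum
|amplitude| is at its centre by construction, so the LAT annotation rule is
exact on noise-free data. Sampling below 1 kHz cannot place deflections to
within a sample and is rejected. Band-limiting filter emulation is not applied;
traces are generated in-band.

**Capture and restitution.** An S2 at coupling interval CI captures iff
CI ≥ ERP(CL), with ERP(CL) = ERP_min + g·(1 − e^(−CL/τ)) — all-or-none at
tissue level, no local block. The preset restitution parameters are least-squares
fits to the published group means; the wild-type values are slightly convex in
cycle length, which a saturating exponential cannot reproduce exactly, so the
fitted τ is large (2 s, a near-linear regime) and matches the three anchor
cycle lengths to within 0.4 ms. Drive trains are assumed to capture (the
generator rejects cycle lengths at or below the tissue ERP); rate adaptation of
APD is not modelled.

**Action potentials.** A single-sample depolarization to the peak at a commanded
upstroke time (default 50 ms, leaving a generous baseline), a short plateau
(2.5 ms, clamped to half of APD20), then linear segments through the three
repolarization anchors (peak − f·amplitude at upstroke + APDf for f = 0.2, 0.5,
0.9); the terminal limb continues the 50→90% slope to rest so the 90% level is
crossed without a slope break. Optional i.i.d. Gaussian noise (presets: 0.5 mV).

## Measurements

**LAT.** Baseline = median of a 20 ms pre-stimulus window; detection threshold =
5 robust SDs (1.4826 × MAD) of that window, configurable. The annotation is the
maximum |deviation| within (stimulus + 2 ms blanking, stimulus + min(CL,
100 ms)); ties resolve to the earliest sample. The integer-sample peak is then
refined by evaluating the Whittaker–Shannon (sinc) interpolant on a 10 µs grid
over ±1 sample, using a ±10 ms support window: the deflection is band-limited
far below Nyquist at 2 kHz, so the refined peak is accurate to a few
microseconds on noise-free data. Without sub-sample refinement the 0.5 ms
sampling grid alone would inject ~30% errors into triangle gradients at these
speeds and grid pitch, which is why refinement is part of the detection
contract here. Thresholding is purely relative to baseline noise, making
annotation invariant to overall amplitude scaling; a zero-noise channel accepts
any nonzero deflection and reports none when the trace is silent.

**Capture detection.** A stimulus captures when ≥ 80% of channels (configurable)
show a supra-threshold deflection in its search window. The per-channel test is
the same baseline/threshold rule without sub-sample refinement, vectorized
across channels, so every delivered S2 can be checked cheaply.

**CV.** Each grid cell splits into two right triangles along the lower-left →
upper-right diagonal (fixed for determinism). The plane through the three
(position, LAT) vertices gives the local gradient (a, b); speed = 1/‖(a, b)‖,
direction = (a, b)/‖(a, b)‖. Triangles with an unannotated vertex or zero
gradient are excluded and counted, never errors; no outlier exclusion is
applied by default (a speed cap is available but off). Mean CV pools triangle
speeds over the last five drive-train beats per cycle length.

**Phase distribution and CHI.** All overlapping 2×2 quadruplets (16 on 5×5)
contribute max(LAT) − min(LAT) per beat; quadruplets with missing channels are
skipped; values pool across the same five beats before percentiles are taken
(pooling, rather than per-beat CHI averaging, was an open choice and is recorded
in every report). CHI = (P95 − P5)/P50 with linear-interpolation percentiles at
position p(n−1); the convention is stamped into the report JSON and mirrored by
the brute-force oracle in the tests. A distribution with zero median (perfectly
uniform map) makes CHI undefined and raises a dedicated error; the pipeline
records a null. Under corner pacing even a homogeneous substrate produces a
curved wavefront and hence a small positive CHI (~0.1), so the undefined case
arises only for genuinely degenerate maps such as planar waves aligned with the
grid.

**TAT.** max(LAT) − min(LAT) per map; the per-cycle-length report carries the
mean over the five pooled beats.

**APD.** Activation time = completion sample of the maximum first difference
before the voltage peak (earliest on ties). Resting potential = mean over a
40 ms window ending 1 ms before the upstroke. On noise-free traces the peak is
the raw maximum and each APDf is the first post-peak crossing of
peak − f·amplitude by linear interpolation between samples — exact for
piecewise-linear waveforms. On noisy traces the peak comes from a 5-point
median filter (no overshoot at the step-like upstroke, unlike polynomial
smoothers) and the crossing is refined by a local fit: samples between the
adjacent standard repolarization levels (80% of the way to each, 70% toward
rest) are selected on a median-filtered copy and restricted to the contiguous
run around the preliminary crossing, then a continuous two-segment line model
with its knot iterated to the crossing is fitted; when an F-test (threshold 8)
finds no detectable slope break, the plain line fit supplies the crossing.
Rationale: piecewise repolarization waveforms change slope exactly at the
measured level, so a naive first-crossing or single-line fit is biased there,
while a free-knot fit wastes variance. With 1 mV noise on a 100 mV action
potential this estimator reaches ~0.15–0.18 ms SD at the shallowest (APD90)
slopes, close to the local information limit at 2 kHz — individual realizations
can therefore still exceed half a sample a few times per thousand, which is why
validation asserts recovery of the mean plus a ≥95% per-realization rate rather
than a universal bound.

**ERP.** The sweep decrements the S2 coupling interval by 10 ms from 100 ms and
stops at the first failure; the reported ERP is the largest failing interval,
so it always lies in [ERP_true − 10 ms, ERP_true). If the tissue ERP reaches
the default 100 ms start, the sweep restarts from the drive cycle length
(extended-start rule). When every tested interval captures, an explicit
below-resolution marker is returned — never a fabricated number — and markers
are excluded (with a warning) from triplicate means.

## Pipeline and reporting

`run_preparation(preset, seed)` simulates one preparation and produces a report
with per-cycle-length conduction entries, per-corner × cycle-length ERP
triplicates, APD20/50/90, the ground-truth settings, a config hash and the
conventions above; it is byte-reproducible given (preset, seed). Conduction
mapping uses a dedicated constant-capture 8-beat drive per cycle length from
the LAA corner (the last five beats are analysed, approximating steady state);
ERP sweeps run from both corners. `summarize_groups` emits descriptive
mean ± SEM (sd/√n) tables only — inferential statistics are deliberately out of
scope.

Problem sizes in the validation suite: recovery tests use single preparations
(≈ 4 minutes of simulated recording each, ~13 M samples); the group-contrast
check runs twenty seeded replications of a 6-vs-6 experiment (240 preparations),
chosen to match the study design while keeping the full suite under two minutes
on one core.

## Preset parameters

| preset | mean CV (m/s) | speed CV frac | ERP(min, gain, τ) ms | APD20/50/90 ms |
|---|---|---|---|---|
| wt-young | 0.341 | 0.15 | 45, 76, 2000 | 8.93, 19.94, 49.31 |
| hcm-young | 0.323 | 0.30 | 44, 76, 2000 | 4.74, 12.19, 33.09 |
| wt-aged | 0.353 | 0.15 | 50, 76, 2000 | 8.93, 19.94, 49.31 |
| hcm-aged | 0.251 | 0.30 | 58, 28, 170 | 4.74, 12.19, 33.09 |

Speeds, APD triples and ERP anchors encode published group means as simulation
settings — they are not claims of reproducing animal data. The heterogeneity
fractions have no measured counterpart; 0.15/0.30 were chosen once as a
plausible wild-type/diseased contrast that separates the groups' emergent CHI
by ~3.5 SD at n = 6. Electrogram noise defaults to 0.05 mV (5% of deflection
amplitude), intracellular noise to 0.5 mV.

## What the generator does not emulate

- Fractionated or multi-deflection electrograms, far-field components, motion
  artifacts and electrode drop-out (channels are silent or clean).
- Discontinuous, fibrotic conduction: the smooth log-normal field yields
  emergent CHI of ~0.3–0.7 at the preset settings, well below values measured
  in remodelled atria, whose phase spreads come from conduction block and
  microstructural discontinuity. Group *ordering* of CHI is meaningful here;
  absolute CHI magnitude is not.
- Ionic membrane kinetics, APD restitution, alternans, wavebreak or re-entry;
  capture is all-or-none with no spatial heterogeneity of block.
- Stimulus artifacts (handled in analysis by blanking, but not synthesized).

Passing tests therefore demonstrate that the measurement chain recovers known
ground truth under clean, well-posed conditions — not that it is robust to every
pathology of real recordings.

## Degenerate inputs and tie-breaks

Equal maximal deflections annotate the earliest sample; equal maximal upstroke
slopes take the earliest; collinear triangle geometry and zero-gradient
triangles are excluded with a logged count; maps need ≥ 3 annotated channels to
enter conduction analysis and ≥ 2 for TAT; CHI warns below 20 phase values and
refuses a zero median; file readers reject (never repair) malformed input,
naming the missing header key or the offending line.
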