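# Methods

This note documents the models, estimators and numerical choices behind
each module, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable choice
existed.

## Transport simulation

A transport scene is a 20 µm nerve segment imaged for 426 s at 4.26 s per
frame (100 frames), matching the in-vivo protocol the pipeline targets.
Moving organelles arrive at the segment's entry ends — anterograde at
x = 0 moving toward the terminal (+x), retrograde at x = L moving toward
the cell body — as independent Poisson processes with per-direction rates
in insertions·min⁻¹. Poisson arrivals are the minimal memoryless
assumption; nothing in the measurement depends on it beyond the recovery
tests, where it makes the expected midpoint-crossing count analytic.

Each mover draws a per-particle constant speed from a normal distribution
(defaults: anterograde 0.45 ± 0.08 µm/s, retrograde 0.35 ± 0.08 µm/s,
clipped at 5 % of the mean) and may skip any frame interval with
probability `pause_prob_per_frame`. These regimes are of the order of
mitochondrial transport speeds in larval nerves; the rates
(1.2 / 0.8 min⁻¹) were fixed once as a plausible control regime —
the original study deposits no raw data to calibrate against, so these
defaults define the simulation conditions rather than reproduce animal
numbers.

**Burn-in.** Insertion runs from 1.5× the pause-corrected traversal time
*before* frame 0, so the segment is statistically stationary when
recording starts. Without burn-in, a cold-start segment under-counts
midpoint crossings by roughly t_transit/T (≈5 % here), which would make
the flux estimator look biased when it is not. Insertion counts reported
by the truth refer to insertion times inside [0, duration] only, so the
Poisson oracle is unaffected.

**Bleaching.** A particle located inside the bleach window at bleach time
is dark from then on (fluorophore destruction); particles entering later
stay bright. This is the property that makes bleaching useful: it removes
the stationary background without touching the flux of incoming cargo.

**Rendering.** Particles become isotropic Gaussian spots (σ = 0.3 µm) on
the mid-row of a 4 µm-tall canvas at 5 px/µm, over a constant background
(10) with additive Gaussian noise (default amplitude 100, noise σ = 2 in
the simulated studies — a high-SNR confocal regime; the original work
reports no SNR, so this is a stated choice, swept implicitly by the
noise-free oracle tests on one side and the stochastic recovery tests on
the other). Not emulated: 3-D optics, z-sectioning, photobleaching decay
over time, detector noise statistics, nerve drift. Passing tests therefore
show that the *measurement logic* is correct under idealised optics, not
that the tracker would survive arbitrary real-data pathology.

## Kymograph analysis

`build_kymograph` samples the stack along a nerve polyline at 1 px steps,
taking the maximum across the path normal (default width 3 px); z-stacks
are maximum-projected first. A bleach event is auto-detected as a
contiguous position range (runs joined per frame) whose smoothed,
background-subtracted intensity drops by more than half between
consecutive frames; the mask covers that range from the drop frame on.

`extract_traces` detects per-column local maxima above the kymograph
median + 3 MAD (a threshold the original study never states; 3 robust
standard deviations is the conventional choice), refines them to
sub-pixel by parabolic interpolation, and links them across columns by
nearest-to-prediction assignment. The prediction extrapolates each
trace's slope over its last ≤3 samples, which implements the
straightest-continuation tie-break at trace crossings. Numerical guards
that matter, found necessary on simulated crowded scenes:

* a trace whose prediction leaves the kymograph is closed (the particle
  exited) — otherwise an exiting particle chains onto one entering at the
  same end, producing a spurious "stationary" V-trace;
* established traces (≥3 samples) use a tighter assignment gate
  (0.5·v_max·Δt + 2 px) than fresh ones (v_max·Δt), preventing identity
  theft at crossings while still allowing pause/resume steps;
* a trace whose peak was absorbed by a close neighbour (two particles
  within the ~2σ resolution limit produce one peak) may share the merged
  detection rather than being dropped;
* collinear fragments separated by ≤3 frames are stitched back together,
  and traces with an interior position extremum and two substantial legs
  (≥3 µm, ≥3 samples each) are split there — either a true reversal, to
  be counted once per direction, or a chimera from a three-way crossing.

Classification follows the stationarity rule: |net displacement| < 5 µm
within the segment ⇒ stationary; exactly 5 µm counts as moving (the rule
is a strict "less than"). Velocity is the pause-excluded mean step speed
(steps > half a position step), with the net velocity
(displacement/duration) also available since the original estimator is
not specified. Flux counts section crossings of moving traces, attributed
to the trace's overall direction; the fly protocol uses a single midpoint
section over 426 s, the mouse-culture protocol two sections (¼ L and ¾ L)
over 30 min with the two counts averaged.

**Estimator accuracy** (basis for the recovery tests): across 600
simulated control movies, measured flux is 1.165/0.785 min⁻¹ against
simulated rates 1.2/0.8 — a ≈3 % anterograde deficit attributable to
particle pairs entering within the optical resolution limit, which form a
single ridge no detector can split; velocities recover within ~1 %.

## Larva tracking

Segmentation is a global Otsu threshold on the background-subtracted
frame; components above 0.2 mm² become blobs. Length is the geodesic
skeleton length with an end correction (add the distance-transform value
at the two skeleton endpoints, subtract one body width) because thinning
stops short of the body tips by the local half-width; on rendered
capsules this estimator is unbiased with ≈0.1 mm spread at 8 px/mm. A
blob larger than 1.6× a supplied single-larva area prior is flagged as a
touching candidate.

Linking is greedy nearest-centroid over globally sorted distances (hence
invariant to blob order), with one-frame gap bridging. Track speed is the
mean centroid displacement rate over ~0.5 s strides rather than single
frames: at 30 fps a single-frame step is sub-pixel and segmentation
jitter would inflate the estimate several-fold; the half-second base
recovers simulated speeds within 1 %. Track length is the median of
per-frame lengths.

Exclusions are applied in one pass: touching tracks first, then — within
each size group (small [1, 3) mm, large [3, 5] mm; the half-open boundary
keeps the groups disjoint at 3.0 mm) — tracks slower than 10 % of the
group mean, where the reference mean is computed once after the
touching exclusion and not iterated (reproducible, and a single member
group can never self-exclude). Movie summaries average included tracks
per group; experiment statistics treat each movie as one observation and
warn below the protocol's six movies per genotype.

The arena generator renders larvae as straight bright capsules on a
smooth random-heading walk with wall reflection; peristalsis, body
bending and head/tail dynamics are not emulated, so the tracker's
accuracy on real crawling postures is untested here.

## Morphometry

The nerve/NMJ mask is the largest connected component of the
Otsu-thresholded membrane channel, hole-filled. "Bright" is within-mask
median + 3 MAD (again a stated choice; the study quantifies but does not
define its threshold). An accumulation requires *both* channels bright
simultaneously, minimum area 1 µm²; counts are normalised by the
nerve-mask area (per 1000 µm²), the natural reading of the per-area
metric. Diameter statistics use linear-interpolation percentiles
(median, quartiles, 1st/99th). Swelling events are position pairs within
1 µm whose diameter ratio reaches the fold threshold (default 3; the
10-fold figure in the literature is a reported extreme, not a criterion),
with overlapping events merged. NMJ puncta are watershed regions seeded
by local maxima of the Gaussian-smoothed (σ = 1 px) cargo channel —
smoothing is what keeps pixel noise from splitting one punctum — with
density defined as puncta area fraction of the NMJ area. The
degeneration score is a plain weighted sum over category flags
(default weight 1; the original point scheme is only partially described,
so weights are configuration, not assertion), with the retraction flag
gated on the simultaneous absence of the vesicle marker and presynaptic
membrane over a region with intact postsynaptic signal.

## Statistics

Routing is exactly the study's recipe: Shapiro-Wilk per group at
α = 0.05; all normal → Student's t (two groups) or one-way ANOVA with
Tukey-Kramer (more); otherwise Mann-Whitney or Kruskal-Wallis with
Dunn's test. Groups with fewer than three observations cannot be
normality-tested and force the nonparametric route with a warning.
Dunn's test is implemented directly (rank sums, tie correction
ΣT = Σ(t³−t), two-sided normal p); no multiplicity adjustment is applied
unless requested, since the study names the test without stating one.
Note that three equally spaced points are perfectly normal under
Shapiro-Wilk (p = 1), so small well-ordered groups route parametric —
the routing is a pure function of the Shapiro outcomes, nothing else.
Stars: * p<0.05, ** p<0.01, *** p<0.001. Climbing scores are means of
exactly three binary trials per fly, averaged over the cohort (protocol:
50 flies; deviations are noted, not fatal).

## Problem sizes

The simulated studies use deliberately small scenes chosen to exercise
every rule while keeping each analysis reproducible on a laptop: 100-frame
transport movies at 5 px/µm; 20 arena movies of 3 larvae, 6 s at 10 fps
and 8 px/mm for the locomotion recovery; 200 seeded replicates for the
estimator-recovery checks and 30 matched pairs for the bleach comparison.
The statistical structure (rates, speeds, exclusion triggers, group
boundaries) is independent of these sizes.

## Known limitations

* Co-moving particles closer than the PSF are one ridge; flux undercounts
  them by construction (~3 % at control rates). Real kymograph analysis
  has the same limit.
* The tracker does not model trace reversal as a first-class event; a
  sustained reversal is split and counted once per direction.
* Accumulation-count monotonicity under threshold changes holds for
  uniform-intensity regions; textured regions can split before they
  vanish as the threshold rises.
* The arena walk is not peristaltic and larvae are straight; skeleton
  sizing of strongly curved bodies is untested.
* `make_report` implements the s.e.m.-box / s.d.-line convention and CSV
  tables only; it is not a general plotting layer.
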