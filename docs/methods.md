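# Methods

This note records the models behind each pipeline stage, the parameter
defaults and why they were chosen, the design decisions taken where more
than one reading was defensible, and what the synthetic-data tests do and
do not establish about field data.

## Coordinate frames and track ingestion

Radar fixes arrive as (range, azimuth) about the radar dish, azimuth in
degrees clockwise from true north (the navigation convention; configurable
via `azimuth_convention`).  All analysis runs in a planar east-north-up
frame in meters anchored at the radar origin: at ≤ 800 m range, planar
error is far below the radar's ~2 m positional accuracy.  Geographic
export calibrates a similarity transform (translation, rotation, scale)
from two reference points of known GPS and local position; with exactly
two points the fit is exact and the reported residual is zero, but the
residual is computed so over-determined calibrations surface inconsistent
landmarks.

A *flight segment* is a strictly time-ordered run of ≥ 2 fixes from one
flight of one individual.  The *substantial* filter keeps segments lasting
≥ 30 s in which the bee moved ≥ 15 m from its first fix; both thresholds
are inclusive because the rejection rule is stated on the "less than"
side.  Rejected segments are retained — they still document where drones
flew and feed the occupancy maps — but take no part in classification or
dynamics.

## Straight / convoluted classification

For every consecutive fix pair the transition bearing is
θ = atan2(Δx, Δy) (clockwise from north).  The resultant vector length of
the n bearings whose transition midpoints fall in a closed 21 s window is
R = |Σ (sin θᵢ, cos θᵢ)|/n: 1 for perfect alignment, → 0 for balanced
dispersion.  Defaults: window 21 s (seven radar rotations at 3 s
sampling), threshold R > 0.7, gap rule 12 s *and* 40 m, minimum
convoluted run 7 fixes.

Decisions taken where the procedure admits more than one reading:

* **Window anchoring.** Windows are evaluated centered at every fix time;
  a fix "falls within" a window when either of its incident transitions
  has its midpoint inside the window interval.  Centered anchoring is
  symmetric and reproduces the seven-rotation span at nominal sampling.
  A fix is a straight candidate iff *any* window containing it has
  R > 0.7.
* **Undefined bearings.** A zero-displacement transition has no bearing
  and is excluded from window statistics; its incident fixes inherit
  candidacy from the remaining bearings.  A window with fewer than two
  defined bearings has undefined R and certifies nothing (a single
  bearing always has R = 1).  A fix all of whose windows are undefined is
  a convoluted candidate — hovering is not straight flight.
* **Gap severing.** A transition with gap > 12 s *and* step > 40 m cannot
  be interior to a convoluted section: it severs candidate runs before
  the minimum-run rule is applied, and it also splits adjacent convoluted
  sections.  Straight sections are simply the maximal leftover runs.
* **Short segments.** A segment shorter than one window cannot support
  any window statistic and is labelled straight with a warning.

The classifier is scale free (with the metric gap rule disabled) and
rotation invariant, and lowering the threshold never increases the number
of convoluted fixes; all three properties are regression-tested.

Known behavior at behavior switches: fixes within half a window (10.5 s)
of a genuine switch between straight and convoluted flight can be
certified straight by windows dominated by the straight side, so section
boundaries are eroded by roughly two to three fixes, and convoluted bouts
whose surviving run falls below seven fixes are relabelled wholesale.  On
unstructured (harmonic-well) convoluted flight there is additionally an
irreducible false-straight rate of a few percent from chance alignment of
~7 nearly independent bearings (P(R₇ > 0.7) ≈ e^(−7·0.49) ≈ 3% per
window).  These effects bound per-fix accuracy on simulated ground truth
at about 90% under the default study conditions; the acceptance suite
measures this directly.

## Congregation-area discovery

Convoluted sections whose center of mass lies within 50 m of a hive are
excluded (hive-front swarming is not lek behavior); by default only hives
active at the flight's start time count, with a strict any-hive flag for
datasets without timestamps.  The remaining convoluted fixes are
clustered with single-linkage agglomeration cut at 8 m Euclidean distance
— equivalently, connected components of the ≤ 8 m adjacency graph, which
is how the implementation computes it for large inputs (KD-tree +
union-find; the scipy hierarchy route is used otherwise and the two are
cross-checked).  Complete and average linkage are available behind the
`linkage` option but change the meaning of the cutoff.  Clusters fed by
≥ 10 distinct flight segments become congregations, labelled A, B, C… in
descending order of contributing segments.  Centers are cluster centers
of mass — robust to perimeter points, unlike the convex hulls, which are
attached for illustration only.

## Swarm dynamics

Within a convoluted section assigned to a location (nearest center within
50 m; a tie between a congregation and a hive goes to the congregation),
positions are expressed relative to the center.  Velocity is the
per-transition displacement over its time difference.  Acceleration
differences consecutive velocities over the *trailing* transition
interval, and the sample sits at the fix shared by the two transitions
(`dt_mode="mean"` divides by the mean of the two intervals instead — the
source procedure does not specify which interval, so both are
implemented).  Samples flanking a severed gap are dropped.

The potential-well fit is unweighted OLS of an acceleration component on
the matching position component, pooled over all sections at one
location.  Under a linear restoring force a = −k(x − c), the slope
estimates −k and the x-intercept −intercept/slope estimates c.  With 3 s
sampling and measurement noise the slope magnitude is attenuated
(finite-difference and errors-in-variables bias), but the x-intercept
remains centered on c by symmetry — which is why center recovery, not raw
stiffness, is the meaningful field statistic, and why stiffness recovery
is tested on finely sampled simulations (0.1 s steps), where the only
bias is the O(γ·dt) discretization term.  Binned profiles (5 m bins over
±50 m, empty bins flagged) visualize the same relationship.

Kurtosis uses the Pearson convention m₄/m₂² (Gaussian = 3), matching the
default of the numerical environment the analysis tradition comes from.
Gaussian-core diagnostics are standardized normal-probability pairs
(sorted values vs Φ⁻¹((i−½)/n)).

A flight visits a congregation if a convoluted section's center of mass
lies within 50 m of the area center, or if it stays within 50 m for
≥ 21 s; runs of consecutive in-disc fixes bridge signal-loss gaps
automatically (a dropout whose flanking fixes are both inside extends the
run), matching the rule that lost signal counts when the bee was inside
on both sides.

## Occupancy heat maps

Between consecutive fixes the position is a Brownian bridge observed with
error: at fraction a of a transition of length dt, an isotropic Gaussian
centered on the linear interpolant with variance
a(1−a)·dt·σ_mob² + σ_loc².  Timeslices are evaluated at interval
midfractions (j+½)/n with n = ⌈dt · 5⌉ slices, so consecutive bridges do
not double-count their shared endpoint.  σ_loc defaults to 2 m (radar
accuracy).  σ_mob is not identifiable from the data model alone; the
default 2.31 m/√s puts the mid-gap bridge sd of a nominal 3 s transition
at 2 m, i.e. the interpolation is allowed to wander about as far as the
measurement error — configurable for faster or slower fliers.

Pixel masses are computed by exact rectangle integration (products of 1-D
normal CDF differences, valid because slices are axis-aligned isotropic).
A midpoint rule (density at pixel center × area) is available behind
`method="midpoint"` but under-counts by ≈ 2·e^(−2π²σ²/h²) — about 8% at
σ = 2 m on 5 m pixels — so the exact rule is the default; per-timeslice
mass conservation to 10⁻³ on covering grids is asserted in tests.

Per-segment grids are normalized so the hottest pixel equals 1 before
aggregation, so no single segment can dominate a pixel and a hotspot
requires multiple independent tracks.  Heat maps consume *all* segments,
including non-substantial ones.  Display opacity ramps linearly between
the 1st and 5th percentile of the aggregated values, computed over
nonzero pixels only — the untouched background would otherwise saturate
the ramp.

## Synthetic data generator

The generator emulates the radar study's conditions with known per-fix
behavioral labels (commute / swarm / hover), planted congregation centers
and bout logs:

* **Swarm bouts** follow the damped harmonic well
  dv = (−k(x−c) − γv)dt + σ dW per axis, Euler–Maruyama at dt = 0.1 s
  (30 substeps per radar rotation; integration requires γ·dt < 1).
  Stationary position and velocity are Gaussian with variances
  σ²/(2γk) and σ²/(2γ), and the conditional mean acceleration is
  −k(x−c).  Defaults k = 0.05 s⁻², γ = 1 s⁻¹, σ = 5.66 m s⁻³ᐟ² give a
  per-axis velocity sd of 4 m/s (mean planar speed ≈ 5 m/s, the observed
  congregation flight speed), a position sd of ≈ 18 m (matching the
  observed 30–50 m core diameters), and a velocity decorrelation time of
  ~1 s — fast enough that bearings at 3 s sampling are nearly
  independent, which is a precondition for windowed-R classification to
  discriminate convoluted flight at all.
* **Commutes** fly at 4.8 m/s (the observed mean straight-section speed)
  along the bearing to the target plus an AR(1) heading perturbation
  (stationary sd 0.1 rad, ~1 s persistence), arriving within 5 m.
* **Hive hover** mixes two wells (tight: k = 0.5, γ = 1, σ = 3; wide:
  k = 0.05, γ = 0.6, σ = 2) in sub-bouts, making hive flight slow
  (~2 m/s at the fix scale) and leptokurtic (position kurtosis > 4) — a
  stand-in that creates the observed hive-vs-congregation contrast, not a
  mechanistic claim about hive-front behavior.
* **Dwell times** are shifted exponentials: swarm bouts
  21 + Exp(113) s, so the realized mean equals the observed 134 s mean
  convoluted-section duration while every bout stays above the
  seven-rotation detectability floor (a plain max(Exp, 21) draw would be
  censoring and put a ~15% atom exactly at the floor); hive hover uses
  mean 140 s (the observed hive-section duration).
* **Radar sampling** reads the path every 3 s, keeps each fix with
  probability 0.9 (dropouts are described as frequent, on one or several
  sweeps), adds 2 m Gaussian noise per axis, and discards fixes beyond
  800 m.
* **Flights** start and end at the drone's home hive: hover, then
  commutes to 1–3 distinct areas with swarm bouts, then return.  A
  configuration with zero bouts produces out-and-back commutes with hover
  only at hives.  Default datasets use 3 hives, 4 areas, 30 drones × 2
  flights; everything is deterministic under the config seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about field data: looping structure inside convoluted
flight (the well model produces unstructured jitter; real drones loop,
which if anything makes windowed-R discrimination easier), altitude and
its effect on detectability, radar shadows and systematic (rather than
independent) dropouts, wind and terrain, orientation-flight ontogeny,
partial segments that begin or end mid-flight, and inter-individual
variation in speed or dwell.  Recovery results (congregation centers to a
few meters, well stiffness within a few percent on fine-grained paths)
are statements about the pipeline's correctness under the generative
model, not about biological effect sizes.

## Numerical and testing notes

Problem sizes were chosen so the full suite runs in well under a minute
of simulation time: five replicate 60-flight datasets for classifier
ground-truth recovery, 100 random instances (≤ 200 points) for the
clustering-vs-components oracle, 6 000–110 000 s single-well runs for
stiffness/variance recovery (longer for softer wells, whose position
autocorrelation time γ/k is longer), and 10⁵ Monte-Carlo draws for the
bridge oracle.  Degenerate inputs are defined errors, not silent
behavior: negative ranges, non-monotone timestamps, zero-variance
kurtosis, constant-position regressions, non-positive bridge intervals
and mismatched grid specs all raise.  Tie-breaks are fixed and
documented: boundary candidacy toward convoluted, equidistant location
assignment toward the congregation, congregation ordering by segment
count then fix count then center coordinates.
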