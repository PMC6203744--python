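# Methods

This note documents the models, conventions, and numerical choices behind
`mousepheno`, in enough detail to reproduce or audit any number the
package computes.

## Coordinate and protocol conventions

All positions are in centimetres in an arena-centred frame; time is in
seconds. Compass start positions N/W/S/E sit on the pool perimeter at
90/180/270/0 degrees (counter-clockwise from +x); release points are
inset 4 cm from the wall. Quadrants 1..4 are the four 90-degree sectors
counted counter-clockwise from the `quadrant_axes_deg` orientation
(default 0), assigned half-open — a boundary angle belongs to the sector
it opens, and the exact centre (whose angle is undefined) falls in
quadrant 1. The platform sits on its quadrant's bisector at radial
distance `diameter/4` (38.5 cm), i.e. half-way between centre and wall.
Trial caps: 60 s (swim), 30 s (probe), 1200 s (open field). Tracked
points may fall up to 1 cm outside the wall (tracking jitter) before a
trajectory is rejected.

## Trajectory metrics

Paths are treated as piecewise linear between samples. Region-restricted
quantities are computed by **exact parametric clipping** of each segment,
never by sample counting, so all metrics are stable (within 2% by test)
under resampling of the same continuous path at dt between 0.04 and
0.2 s — important because commercial trackers' sample rates vary:

- *Corridor error index*: each segment is clipped against the 20-cm-wide
  rectangle from the start point to the **platform centre** (the corridor
  is capped at the centre, the simpler monotone convention, with the
  boundary inclusive). Length-weighted by default; a time-weighted
  variant is available (`weight="time"`). In-corridor and off-corridor
  shares sum to 100 exactly.
- *Path efficiency ratio* = path length / direct distance, where the
  direct distance runs from the start to the platform's **near edge**
  (centre distance minus the 12-cm platform radius). A swim terminates at
  platform contact, so the edge convention is what makes a perfectly
  straight escape score exactly 1.0 and keeps the ratio >= 1 in general;
  pass `platform_radius_cm=0` for the centre convention.
- *Latency*: first time the tracked point comes within the platform
  radius of the platform centre, with the crossing instant interpolated
  inside the straddling sample interval; trials with no contact are
  censored at the 60-s cap and flagged.
- *Quadrant occupancy*: each interval is split exactly where the
  interpolated path crosses a quadrant axis and each piece is assigned by
  its midpoint; shares are time-weighted and sum to 100.
- *Central-zone path*: segments clipped against the zone circle
  (quadratic roots), default zone the open field's 52-cm-diameter disk.
- *Binned speed*: 5-min (300-s) windows; the session must tile into
  whole bins (the 20-min protocol gives exactly four), and a leftover
  partial bin raises rather than being silently averaged.
- *Stops*: the instantaneous speed (per-interval displacement rate) is
  smoothed with a 0.5-s centred moving average; a stop is a maximal
  interval below 2 cm/s lasting at least 1 s. The criterion is this
  package's definition (commercial trackers do not publish theirs);
  all three parameters are exposed.
- *Strides*: the hindlimb coordinate along the beam axis is segmented
  into stance phases (speed below 10 cm/s for at least 0.05 s; the
  threshold sits far above 60-fps tracking-noise jitter of a few cm/s
  and far below ~60 cm/s swing speeds). Stride k is the distance between
  the median positions of stances k and k+1; fewer than two stances
  (continuous sliding) is an error.

## Search-strategy classifier

Features per swim (zone shares time-weighted with trapezoidal sample
weights; efficiency/corridor/coverage path-based): efficiency ratio,
corridor fraction, wall-band share (within 8 cm of the wall), chaining-
annulus share (radial distance within 10 cm of the platform's 38.5-cm
orbit), inner-zone share (inside half the pool radius), proximity shares
(within 30 cm of the current and, when defined, previous platform),
target-quadrant share, and pool coverage (visited fraction of the
pool-interior cells of a 10x10 overlay; retained for diagnostics, unused
by the default rules).

The cascade assigns the first matching rule:

1. **DSw** if efficiency <= 1.3 and corridor fraction >= 0.8
2. **DSe** if corridor fraction >= 0.7
3. **FS** if target-proximity share >= 0.5
4. **P** if previous-platform-proximity share >= 0.5 (skipped when no
   previous platform is defined)
5. **T** if wall share >= 0.65
6. **C** if annulus share >= 0.7
7. **S** if inner-zone share >= 0.6
8. **RS** otherwise

Spatial rules precede non-spatial ones so near-goal behaviour dominates
ambiguous paths, and P precedes T/C/S so perseverative focal search at
the old goal is not absorbed by scanning. Every threshold is a field of
`ClassifierThresholds`. The rule set replaces manual two-rater
categorization; since human raters' quantitative criteria are not
published, the thresholds are validated against simulated archetypes
(macro recall >= 0.80 at default heading noise; exact recovery of
noise-free archetypes), not against human labels — passing says the
cascade separates the kinematic archetypes, not that it matches any
particular rater.

Spatial percentage = share of {DSe, FS, DSw, P} labels; improvement rate
= last-day minus first-day spatial percentage (may be negative).

## Synthetic-data generators

The generators encode the study conditions the analysis targets and emit
ground truth alongside the data; all are reproducible from a seed.

**Swim trials** are correlated-heading walks at fixed speed (dt default
0.1 s): each step the heading relaxes to a strategy-specific desired
direction and receives von Mises noise (default sd 0.3 rad/step; 0 gives
deterministic archetypes). Steering rules: DSw heads at the platform;
DSe adds a 1.5-rad sinusoidal zigzag (1.2-s period) about the platform
bearing, elongating the path past the DSw efficiency cut-off while
staying in the corridor; FS approaches an anchor near the platform and
then orbits it on a slowly tightening ring (19 -> 13 cm); P does the
same at the *previous* platform, approaching via the pool centre so the
return leg cannot accidentally cross the current platform; T orbits
5 cm off the wall; C orbits the platform's 38.5-cm ring, entering in the
direction of the longer arc so the chaining ring is actually travelled;
S wanders, steered back to the centre beyond 30 cm; RS is an unbiased
correlated walk launched 44-55 degrees off the inward bearing (so its
opening chord cannot skewer the platform) with billiard reflection at
the wall. A trial ends at first platform contact — the final sample is
clipped to the exact contact point, so path length and latency carry no
step-overshoot error — or at the 60-s cap. Group speed presets, 0.22 and
0.31 m/s, emulate the published strain means.

**Cohorts** draw each trial's strategy from a per-day mixture. The
control-like schedule raises the spatial weight 0.44 -> 0.87 across the
five reversal days; the model-strain-like schedule stays nearly flat
(0.31 -> 0.36) — matching the published day-1/day-5 spatial-use figures.
Within categories the split is DSe .5 / FS .2 / DSw .2 / P .1 and
RS .35 / S .25 / C .25 / T .15 (the published account emphasizes DSe
dependence, late FS/P appearance, and RS/C persistence in the impaired
strain). With 4 trials x n mice per day, a day's realized spatial share
carries binomial noise (sd ~7 points at 48 trials).

**Open field**: a bounded correlated walk (move speeds 0.13 / 0.24 m/s
for the control-/model-strain-like presets, pause onset 1/60 / 1/90 per
s) alternating with explicit pause episodes (uniform 2-4-s dwell, 0.05-cm
stationary jitter). A 3-s refractory gap follows each pause and none
starts close enough to the session end to be truncated, so the episode
count is unambiguous ground truth for the stop detector. The presets
give ~0.12 vs ~0.23 m/s session speeds, matching the published
locomotion contrast.

**Beam**: stance plateaus (0.18 s) alternate with smoothstep swings
(0.12 s) at 60 fps with 0.03-cm tracking noise; strides are drawn
N(8, 0.5) cm and never carry the limb past the 92-cm beam.

**Section images**: dark disks (intensity uniform in [105, 150], inside
the [90, 180] detection band) of radius 5-9 px on a 230-background
512x512 uint8 field; disjoint disks keep >= 4-px clearance; touching
pairs are placed with ~1.5-px overlap so they rasterize as one
8-connected blob.

What the generators do **not** emulate: swim-speed variability within a
trial, learning within a day, thigmotaxis-to-search transitions inside a
single swim, video artifacts (dropouts, identity swaps), staining
gradients, non-circular or overlapping-by-more-than-a-neck cells.
Passing tests therefore demonstrate correctness of the measurement and
classification machinery under clean kinematics, not robustness to every
artifact of real tracking or histology.

## Morphometry

Volume = `sum(section areas, mm^2) x 0.040 mm x 5` (40-um slices, every
5th sampled). Isolated interior missing sections are imputed as the mean
of their flanking sections; runs of missing sections and missing edge
sections cannot be imputed, and three or more missing sections reject
the brain. Cortical thickness is aggregated as arithmetic means overall,
by measurement point, or by hemisphere, with missing cells excluded.

Particle counting thresholds the image to the inclusive [90, 180] band
(RGB converted via luminance; 16-bit inputs rescaled to the 0-255 scale
by /257 — the classical tool leaves this ambiguous, and this is the
convention chosen here). With watershed on, markers are the local maxima
of the Gaussian-smoothed (sigma 1 px) Euclidean distance transform with
5-px minimum separation, one per convex core; the watershed then carves
a 1-px divide line, and the label image is used directly (re-binarizing
would re-merge halves under the 8-connectivity used for components).
Components are filtered by pixel area (default 0..inf) and circularity
4&pi;A/P&sup2; with the perimeter from contour tracing, clamped at 1.0
since digital perimeters of small disks overshoot (default range 0..1
keeps everything, as in the classical defaults).

## Statistics

All tests are two-tailed at alpha 0.05. U is min(U1, U2) from midrank
sums; the p-value is exact by full enumeration when n1+n2 <= 16 with no
ties, otherwise the tie-corrected normal approximation with continuity
correction (which rejects ~4.4% of null cases at the n = 9 vs 13 group
sizes — slightly conservative, as expected of the continuity-corrected
approximation). Kruskal-Wallis uses the chi-square approximation, with
the all-identical-groups case short-circuited to H = 0, p = 1. Spearman's
rho uses exact permutation enumeration for n <= 7 and the t
approximation above. Bonferroni multiplies by the declared family size,
capped at 1, and records the family size; which comparisons form a
family is a configuration choice (`run_report` treats its per-metric
group comparisons as one family).

## Problem sizes

The test suite and `scripts/acceptance.py` use: 50 trajectories for
metric-oracle equivalence, 100-200 simulated swims per strategy class
for recovery rates, cohorts of 5-12 mice per group (4 averaged replicates
in the acceptance script), 60-100 disjoint-disk and 20-25 touching-pair
image fixtures, and 10,000 null simulations for the U-test calibration.
These sizes keep every run to seconds-to-minutes on one CPU while
leaving the binomial noise on reported percentages small relative to the
effects of interest.

## Known limitations

- Classifier thresholds cannot be validated against human raters (no
  labelled data exist); they are validated against simulated archetypes.
- The corridor is capped at the platform centre; capping at the edge
  would shorten the corridor by one platform radius and slightly raise
  the index for direct swims.
- Watershed separation is tuned for cell-sized convex blobs; chains of
  three or more merged cells may split imperfectly (the +-5% aggregate
  tolerance on touching-pair fixtures reflects this).
- `kruskal_wallis_h` p-values are approximate at very small n; use
  `mann_whitney_u` (exact) for two-group designs.
- Slip counts on the beam are pass-through metadata; the package does not
  detect slips from kinematics.
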