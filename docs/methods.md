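# Methods

This note documents the models, conventions and numerical choices behind
`barnestrat`, in the order data flows through the package.

## Arena model and conventions

The maze is modelled as a disk of radius 46 cm with 20 holes of radius 2.5 cm
centred on a 40 cm ring — the dimensions of common commercial mouse Barnes
mazes.  All of it is configurable (`ArenaSpec`), and every module takes the
arena as an explicit argument.  Coordinates are centimetres with the origin at
the arena centre, y up, angles counter-clockwise from +x; hole `k` sits at
angle `2πk/n_holes` and the escape (target) hole is an index, default 0.

A *hole visit* is proximity-based: a tracked point belongs to a hole when it
lies within `visit_radius` (default 7 cm) of that hole's centre, nearest hole
winning where zones overlap.  The 7 cm default approximates a nose-poke zone
larger than the hole itself; because adjacent holes on the default ring are
~12.5 cm apart, the visit zones of neighbouring holes slightly overlap and a
path that runs along the ring registers every hole it passes.  The *target
quadrant* is the 90° sector centred on the target hole (not axis-aligned),
since the quadrant of interest is defined relative to the escape location.
Commercial tracking systems do not publish their proximity or quadrant
conventions; these are declared defaults, not claims of equivalence.

## Tracking ingest

Input is generic tracking CSV (one trial per file) plus a manifest CSV with
trial metadata.  A *dialect* maps column names and applies a pixel-to-cm scale
and origin shift, which covers most tracker exports without bespoke parsers.
Rows with non-finite coordinates are dropped (with a reported count); gaps
longer than `max_gap` (default 1 s) raise a QC warning rather than silently
fabricating positions.  Analysis runs on trajectories smoothed with a centred
moving median (default window 5 samples — robust to single-frame tracking
glitches) and resampled to uniform `dt = 0.1 s` by linear interpolation,
which gives coverage and dwell-time features a defined sampling basis at
typical 25–30 fps recordings.

## Per-trial features

All features of a training trial are computed on the trajectory truncated at
*escape* — the first entry into the target hole's visit zone; trials that
never reach the target use the full trajectory and carry `reached_target =
False`, with `escape_latency` set to the trial duration.

* **path efficiency** = straight-line distance from the first sample to the
  target hole centre ÷ path length up to escape.  Because trials can end at
  the visit-zone boundary (7 cm short of the hole centre), efficiency can
  slightly exceed 1; it equals 1 exactly for a straight run whose last sample
  is at the hole centre.
* **total coverage** = fraction of square grid cells (default side 4 cm,
  roughly a body width) intersecting the arena disk that contain at least one
  sample.  This is the simplest monotone, unit-free occupancy definition; it
  is declared, configurable, and not claimed to match any proprietary
  implementation.  Grid occupancy is exactly invariant under quarter-turn
  rotations (which the tests exploit) but only approximately invariant under
  arbitrary rotations.
* **centroid to target** = distance from the unweighted mean sample position
  to the target hole centre ("platform" in water-maze vocabulary).
* **hole sequence / primary errors** — collapsed visit list (re-entries to the
  same hole within a 1 s refractory merge) and the count of non-target visits
  before the first target visit.

Open-field trials are summarised by distance, mean speed and time in a centred
square whose side is half the box side (default 50 cm box).

## Strategy classification

The classifier is a deterministic decision cascade over the features, most
target-directed strategy first; the first matching rule wins, so every trial
gets exactly one label.  The rules and their default thresholds
(`ClassifierParams`) are:

1. **direct** — target poked first, ≤ 1 primary error, efficiency ≥ 0.7.
2. **short chaining** — ≥ 2 visits, first visit within 3 holes of the target,
   hole-to-hole steps ≤ 1, never beyond the 3-hole band, revisit-free,
   efficiency ≥ 0.45, ending at the target.
3. **long chaining** — the entire visit sequence is one monotone approach
   chain (steps ≤ 1, circular distance to target strictly decreasing) of ≥ 4
   visits starting more than 3 holes out and ending at the target.
4. **serial** — ≥ 3 visits, steps ≤ 1, revisit-free: a systematic sweep
   without the monotone-approach structure (e.g. one that first moves away
   from the target and wraps around the ring).
5. **random** — scattered or disorganised search: mean |step| > 2 holes, any
   step > 1 hole, repeated returns to already-searched holes, or a sparse
   (≤ 2 visits) low-efficiency find.
6. **focal incorrect** — fewer than 2 visits, coverage < 0.1, centroid more
   than half the ring radius from the target and within a visit radius of a
   non-target hole: persistent search in one wrong place.
7. **unclassified** otherwise (e.g. a stationary trajectory).

Design notes.  Requiring the long chain to span the *whole* visit sequence
(rather than merely terminate the trial) is what separates target-directed
chaining from a wrap-around serial scan, which necessarily ends with holes
adjacent to the target.  The revisit-free and efficiency conditions on chains
separate executed chaining from a meander that incidentally ends next to the
target: in simulation, disorganised walks that slide along the ring produce
chain-shaped visit sequences but revisit holes and travel several times the
straight-line distance.  `direct_max_first_hole_dist` defaults to 0 because,
with overlapping visit zones on a standard ring, a chaining trial starting one
hole out would otherwise satisfy the direct rule.  All thresholds were
calibrated only against this package's own simulator; byte-level equivalence
with any published or proprietary classifier is explicitly not claimed, and
the vocabulary beyond the three hippocampus-dependent strategies is this
package's own taxonomy.

Probe trials can be classified with the same rules but are excluded from
score computation, which is defined over training trials.

## Scoring and statistics

The cumulative strategy score is implemented exactly as stated in the README;
non-hippocampal strategies contribute weight 0.  The per-mouse specialisation
(`mc = 1`) and the pooled cohort formula are algebraically identical under
averaging, and the test suite asserts the identity to 1e-12 on random label
matrices.  Group comparisons use per-animal scores so a two-sample test has
within-group variance; the Welch (unequal-variance) t-test is the default.
Both zero-variance degenerate cases are documented: identical constant
samples give (t=0, p=1), constant samples with different means raise.

The learning-curve ANOVA is a two-way mixed design (between: group, within:
trial) using the standard sums-of-squares decomposition: group is tested
against subjects-within-groups, trial and interaction against the
subject-by-trial residual.  Subjects with missing trials are excluded listwise
with a warning; all-equal inputs report F=0, p=1 by convention.  On balanced
data the table matches `pingouin.mixed_anova`, which the tests use as an
independent oracle.  No sphericity correction or post-hoc procedure is
applied; with three or more groups the same decomposition serves as the
one-way specialisation across groups.

Probe metrics over the first 120 s: collapsed visits to the (closed) target
hole, dwell time in the target quadrant (hole-zone dwell inside the sector
counts), and the time-averaged distance to the target hole centre.

## Synthetic cohorts

The simulator exists to make every stage testable without animal data.  The
movement model is a constant-`dt` (0.1 s) correlated walk: per step the
heading is the aim direction plus von Mises noise (concentration
`heading_kappa`, default 8) and the speed is Gaussian (12 ± 2 cm/s, floored at
1 cm/s).  Walks between holes stop at the hole radius and dwell ~1 s, so zone
entries are robust to smoothing and resampling.  Per-strategy generators:

* **direct** — re-aimed walk from the centre to the target.
* **short chaining** — approach a hole within ±3 of the target, then ±1-hole
  ring steps to the target.
* **long chaining** — approach a hole 5–10 holes out, then a monotone ring
  walk to the target.
* **serial** — approach a uniformly random non-target hole, then sweep the
  *longer* arc to the target (random direction at the antipode, where the
  arcs tie).  Sweeping the longer arc is what makes the scan operationally
  non-target-directed: a scan that happens to take the shortest arc from 5–10
  holes out is behaviourally indistinguishable from long chaining, and no
  classifier could separate the two.
* **random** — correlated random walk with quartered heading concentration,
  reflected at the wall, terminating on a chance target encounter or at 180 s.
* **focal incorrect** — approach the hole antipodal to the target and dwell in
  a ≤ 3 cm-radius slow walk around it for the whole trial.

Cohort simulation draws each (group, mouse, trial) strategy from a
trial-indexed mixture and derives a stable SHA-256 sub-seed per cell, so the
whole simulation is a pure function of the manifest and adding a group never
perturbs existing trajectories.  The built-in profiles emulate a learning
cohort (linear interpolation from 60 % random / 30 % serial / 10 % long
chaining on trial 1 to 50 % direct / 30 % short chaining / 10 % long chaining
/ 10 % serial on trial 9) and an impaired cohort that keeps 50 % random /
35 % serial / 10 % focal / 5 % long chaining on every trial.  Nine training
trials (three per day over three days) is the default protocol.

What the simulator does *not* emulate: thigmotaxis, pauses and grooming bouts,
speed–turning coupling, tracking dropouts, inter-animal variability in speed
or learning rate.  Passing recovery tests therefore shows the pipeline is
internally consistent and discriminative under this movement model — not that
the classifier matches human scoring of real mice.

## Validation problem sizes

The test suite checks, among others: classifier recall on 200 simulated trials
per strategy at default noise (recall ≥ 0.9 for direct/serial/random, ≥ 0.8
for the adjacent short/long chaining pair); score-formula fixed points (a
uniform direct / short / long single-mouse cohort scores exactly 10 / 9.5 /
7); the cohort/per-mouse identity on 1 000 random label matrices; bounds and
upgrade-monotonicity on 10 000 randomized cohorts; group recovery over 100
seeded cohort pairs of 10 mice × 9 trials (Welch p < 0.05 and a negative
Spearman latency trend in ≥ 95 of 100 seeds); and brute-force oracles for the
trajectory features and the ANOVA table.  These sizes keep the full suite
around a minute on one CPU while leaving the thresholds meaningful.

## Known limitations

* The classifier taxonomy and thresholds are simulator-calibrated defaults;
  real deployments should validate them against a hand-scored sample.
* Coverage depends on the grid origin and cell size; compare values only
  within one configuration.
* The mixed ANOVA assumes a balanced within factor after listwise exclusion
  and applies no sphericity correction.
* Serial scans that take the shortest arc toward the target are credited as
  long chaining by construction; the two are not separable from trajectories
  alone.
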