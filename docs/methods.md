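# Methods

## Model overview

`colonypress` simulates early microcolonies of rod-shaped bacteria as 2D
rigid capsules (spherocylinders) whose only coupling is mechanical:
growing cells collide, a budgeted solver pushes them apart, and whatever
overlap the solver cannot remove in time acts back on the cells as
*pressure*. Three consequences are modelled explicitly:

1. **Pressure-dependent growth.** Elongation is delayed — never
   cancelled — in proportion to the pressure a cell has recently felt.
2. **Layer promotion (top-down mode).** A cell that stays over-pressured,
   cannot be moved sideways by the solver, and overlaps a same-layer
   neighbour climbs onto the next discrete z-layer.
3. **Gravity (vertical-section mode).** In a vertical plane, quasi-static
   settling against a ground plane produces the piled cross-section that a
   confocal vertical section shows.

There are no nutrient fields, gene circuits or signalling: the point of
the model is that pressure alone reproduces the architecture — pyramid
cross-sections, a 1-cell-deep outer ring, discrete peripheral layers,
radial age/pressure gradients, and surface-stiffness-controlled monolayer
breaking.

## Physics: budgeted positional solver

Bodies are capsules (segment of half-length `h` swept by radius `r`).
Contact depth between two capsules is `r_a + r_b - d` where `d` is the
segment-segment distance. Candidate pairs come from a uniform spatial
grid whose cell size is the largest body reach plus a margin, so the
broadphase is near-linear in cell count and provably complete for the 3x3
neighbourhood stencil.

Resolution is position-based projection: per iteration each contact
translates both bodies apart along the contact normal by
`beta * depth / 2` each (`beta = 0.5`), with an angular correction
`0.1 * cross(lever, correction)` radians that lets squeezed cells rotate
toward free space and tilted cells lie flat. Iterations repeat until the
deepest contact is below the tolerance `1e-4` um or the per-step *budget*
`B` is exhausted. There are no velocities, impulses or friction cones —
colony growth is so slow that quasi-static projection is the appropriate
regime, and it is fully deterministic.

The per-cell sum of contact depths remaining at budget exhaustion is the
**residual penetration**, the model's pressure reading: "growth faster
than the collision solver" is exactly a nonzero residual. The substrate
reaction (ground-plane penetration in vertical mode) is *not* counted as
pressure: crowding pressure comes from other cells, and counting the
ground would make every resting cell read pressure during settling.

The budget is the model's handle on surface mobility: on soft agar cells
slide easily (the solver has, in effect, more time: `B = 500`); on stiff
agar they are pinned (`B = 12`); standard conditions use `B = 60`. A
power law through these anchors maps numeric agar percentages (1.5% /
3% / 5%) to budgets, strictly decreasing in stiffness.

## Growth, delay and division

Each pole of each cell fires independently at exponential waiting times
(mean 20 steps). A firing adds `dL = 0.1` um of length at that pole (the
opposite pole tip stays fixed) scaled by the growth factor

    f(P) = 1                          P <= P_delay
         = linear                     P_delay < P < 2 P_delay
         = f_min                      P >= 2 P_delay

with `P` the mean residual penetration over the last `W = 10` steps,
`P_delay = 0.02` um and `f_min = 0.2`. The withheld fraction
`dL * (1 - f)` is banked per cell; banked length is paid back at up to one
increment per firing, gated by `(f - f_min) / (1 - f_min)`, so a fully
squeezed cell elongates at exactly `dL * f_min` per firing (interdivision
time 1/f_min times the free mean) while a relieved cell catches up.

Division triggers when total length reaches a per-cell threshold sampled
as 4.0 um +-10%. Daughters split the parent axis at its midpoint (axis
length conserved exactly), inherit the layer, and receive independent
angle jitter Uniform(-0.3, 0.3) rad — asymmetric division angles — plus
fresh pole clocks, a fresh threshold, and an empty pressure window.
Daughter capsules initially overlap near the division site; the solver
resolves that overlap, which is itself a physical push on the
neighbourhood.

`P_delay = 0.02` um was fixed by scanning the signal actually produced by
standard colonies: residuals in the colony core pass 0.02 um around
100-200 cells, so the delay engages over most of a 600-cell run and
produces the radial age contrast; at 0.05 um the delay only engages in
the last ~100 steps and ages stay spatially uniform.

## Layers and promotion

Top-down colonies track an integer layer per cell (1 = substrate). Only
same-layer cells collide; a promoted cell passes freely over its former
neighbours. Promotion of a cell requires, simultaneously:

* pressure signal above `P_up = 0.06` um for `tau = 25` consecutive steps,
* net solver-achieved displacement below `eps = 0.2` um over those steps
  (the solver cannot find collision-free space for it), and
* at least one overlapping same-layer cell (support to climb onto).

Candidates are processed in descending pressure order (ties by id), one
layer per cell per step, and promotion clears the cell's pressure and
displacement windows. These thresholds were calibrated once against the
intended regime: standard-surface colonies break the monolayer centrally
at a few hundred cells, stiff surfaces break at ~100 cells, and the soft
preset never breaks up to 600 cells (an ideal monolayer). They are
exposed in the configuration.

Colony height in top-down mode is discrete: layer count times the cell
diameter, matching the 1-cell/2-cell/3-cell-deep language of microscopy
profiles.

## Vertical sections and gravity

Vertical mode treats the plane as a single physical layer (every pair
collides) with a ground plane at z = 0. Each step performs the collision
solve, then `settle_cycles = 3` cycles of: drop every body by
`gravity_step = 0.1` um and re-solve including the ground constraint.
Three cycles give enough downslope transport per step that the pile keeps
a flat 1-cell-deep rim while the centre grows tall; a single cycle leaves
an unrealistically steep pile with no monolayer edge. The ground contact
applies a flattening torque, so resting cells lie horizontal and a lone
cell's top sits at exactly one diameter.

## The engine step

Fixed order per step: (1) elongate every cell using the *previous* step's
pressure signals (one-step lag avoids a fixed point within the step);
(2) divisions; (3) budgeted solve with the mode's pair eligibility;
(4) vertical: gravity settling — top-down: promotions; (5) pressure /
displacement window updates from the step's solver report; (6) event
logging. One `numpy` generator seeded from the config drives all
randomness; per-cell draws are consumed in ascending cell-id order, so a
(config, seed) pair reproduces a run bit for bit.

Time is in abstract steps. No calibration of steps to hours is attempted
— the experimental milestones (18 h / 22 h / 24 h) are reproduced as
*orderings* of events, not clock times, because no growth-rate
calibration is available for the mapping.

## Metrics

* **Section profile**: vertical mode bins the top envelope of the capsule
  outlines along the substrate axis; top-down mode bins layer-count
  height along a line through the centroid. The monolayer reference is
  the modal height of the outer 15% of occupied bins, taken per flank
  with the smaller flank winning (one doubled edge cannot shift the
  reference).
* **Layer ratios**: occupied bins within 0.25 diameters of an integer
  multiple of the reference form discrete plateaus; the per-plateau
  median height over the reference is the ratio; the rest is the gradual
  fraction (the pyramid core).
* **Transition discreteness**: among non-zero adjacent-bin height changes
  in a region (outer vs middle 30% of occupied bins), the fraction at
  least 0.8 diameters. A 5-bin median despeckle is applied first: the
  envelope of a granular pile carries single-cell surface bumps that
  would otherwise register as spurious jumps in the colony centre;
  plateaus and ramps wider than the filter pass through unchanged.
  One-diameter bins are the intended scale for this statistic.
* **Radial profiles**: per-annulus means of age (steps since birth),
  pressure, layer or generation over normalised radius; empty annuli are
  flagged, never interpolated.
* **Break time**: first promotion event (top-down) or first centroid
  above 1.5 diameters (vertical); `None` if the monolayer never breaks.
* **Age-pressure association**: Spearman rank correlation (no linearity
  assumed) between interdivision age and pressure.

All metrics are pure functions of a snapshot or history.

## Default parameters

| parameter | value | unit | meaning |
|---|---|---|---|
| radius | 0.5 | um | capsule radius |
| birth length | 2.0 | um | founder total length |
| division length | 4.0 +-10% | um | per-cell division threshold |
| dL | 0.1 | um | elongation increment per pole firing |
| pole interval | 20 | steps | mean exponential firing interval |
| P_delay | 0.02 | um | pressure where growth delay starts |
| f_min | 0.2 | – | growth-factor floor (delayed, not cancelled) |
| W | 10 | steps | pressure window |
| theta_max | 0.3 | rad | division angle jitter |
| beta | 0.5 | – | projection relaxation factor |
| angular compliance | 0.1 | rad/um^2 | torque coupling of corrections |
| tolerance | 1e-4 | um | resolved-contact threshold |
| B soft/standard/stiff | 500/60/12 | iterations | solver budget per step |
| P_up, tau, eps | 0.06 um, 25 steps, 0.2 um | | promotion rule |
| gravity step x cycles | 0.1 x 3 | um | settling per engine step |
| separation d | 36 | um | two-colony founder spacing |

Problem sizes used by the test suite and the reproduction script: ten
seeds each of vertical runs to ~400 cells, top-down runs to ~600 cells,
and two-colony runs (d = 36 um) to ~1200 cells — the scale of early
microcolonies, where the architecture of interest (first two or three
layers, first merge) has just formed.

## What the simulations do and do not emulate

The generator emulates: independent stochastic bipolar growth, division
angle noise, crowding mechanics, substrate mobility differences, and
discrete layering. It does not emulate: 3D mechanics (each simulation is
a 2D plane — a vertical slice or a per-layer top-down plane), nutrient or
signalling gradients, cell death or motility, adhesion, or real surface
friction (the solver budget is a proxy). Passing tests therefore
demonstrate that the pressure mechanism suffices to produce these
architectures *in the model*, not that real colonies use no other
mechanism.

## Numerical notes and edge cases

* Degenerate contact normals (coincident closest points, e.g. freshly
  divided daughters) fall back to the centroid direction, then to the
  body normal.
* Residual measurement is a separate non-moving detection pass after the
  last iteration; budget 0 therefore measures without moving anything.
* The broadphase candidate set is built once per solve with a 1 um
  margin; within-solve motion is far smaller in the quasi-static regime.
* Promotion ties are broken by pressure then id; all iteration orders
  are fixed, so runs are reproducible across platforms with the same
  floating-point semantics.
* Snapshot CSVs are written at `%.17g` so reloading reproduces the state
  exactly.

## Known limitations

* Absolute time is uncalibrated; only orderings are meaningful.
* The solver-budget/friction analogy is qualitative; the agar-percent
  mapping interpolates three anchor conditions.
* A promoted cell never returns to a lower layer, and only one discrete
  level exists per promotion event; slanted or partial stacking is not
  represented.
* In vertical mode the measured length of a cell can exceed its division
  threshold by up to one step's growth before the division check fires.
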