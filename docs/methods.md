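# Methods

## Model

The simulator treats the determination of eyespot and parafocal-element
(PFE) rings as a kinematic process on a two-dimensional wing surface, in
abstract units (distances in cell-units, times in time-units; no conversion
to micrometres or hours is attempted).

**Unit signal.** A signal released at time *s* with initial velocity
*v₀* ≥ 0 into a medium of uniform resistance decelerates at a constant rate
*a* < 0:

x(τ) = v₀ τ + ½ a τ², with τ = t − s, valid for 0 ≤ τ ≤ −v₀/a.

At the stopping time −v₀/a the velocity reaches zero and the position is
clamped forever at the final position −v₀²/2a. The implementation returns
the settled position *exactly* (bit-identical to `final_position`) for every
τ at or past the stopping time, so "constant after settlement" holds at
machine precision, not merely within rounding of the evaluated quadratic.

**Bands and trains.** A dark ring is not a pulse: the organiser releases
signal over a window of duration *D* > 0, producing a band whose front is
the unit released at the window's opening and whose rear is the unit
released at min(t, window end). While the window is open the rear sits at
the focus and the band renders as a disc. Because the front stops first and
the rear last, the band narrows as it travels and collapses to zero width on
the common final position — the reason outer rings, which travel farther,
are narrower than core rings (the inside-wide rule). A train stacks *n*
windows separated by pauses *I* ≥ 0; window k+1 opens at window k's end plus
*I*ₖ. (The pause is defined as inner start minus outer end, the sign
convention that makes the canonical two-ring train with D = 3, I = 3 produce
windows [0,3] and [6,9].)

**Settlement.** Two modes: `run_to_settlement` lets every unit stop on its
own (spontaneous velocity loss); `time_out` freezes the whole snapshot at
t_out, the end of the signalling step, capturing bands mid-flight with
strictly positive widths. Repulsive velocity loss is expressed through the
interaction clamps below.

**Interactions.** Applied in this order at query time:

1. *Barriers.* A line element (or an explicit per-ray clamp table) blocks a
   front where its ray crosses it; the rear is clamped by the same barrier
   only once it reaches it. A `soft` mode replaces the hard clamp by an
   exponential approach within a margin (default 2 cell-units) of the line,
   mimicking extra deceleration near an inhibitory element; the soft-clamped
   front never exceeds the free front and never reaches the barrier.
2. *Fusion vs repulsion.* For each organiser pair the first-contact time of
   their outermost fronts is found by bracketing + Brent root-finding on the
   analytic front trajectories. If contact happens before the inhibition
   maturation time `t_inhib`, the pair is fused: no clamp, occupancies
   union (a double-focus eyespot). Otherwise each front is clamped at the
   perpendicular bisector of the joining segment (the mutual midpoint on
   that line), a hard repulsion.
3. *Minimum gap.* Inhibition between consecutive dark rings of one train
   keeps the inner band at least `min_gap` behind the outer band's rear.
   The clamp halts the whole inner band — both front and rear — at the gap
   limit: units piling up there do not pass through it. This is what keeps
   the narrow, nearly constant light rings when the pause *I* is short.

**Treatments.** Tungstate and cold shock slow the signalling step, heat
shock accelerates it. A treatment at time T splits each train: windows not
yet open at T are re-parameterised (v₀ scaled by k_v, D by k_D, the pause
before the window by k_I) and never moved earlier than T; windows already
open keep their parameters and gain a propagation-rate factor k_prop — an
effective-elapsed-time warp — because a signal already in flight can change
only its propagation, not its initial velocity. Defaults are
k_v = k_D = k_prop = 0.6 and k_I = 1.5 for the slowing treatments and the
reciprocals for heat. The magnitudes are not empirically constrained; they
are chosen once to produce the observed qualitative series (smaller
eyespots with proportionally wider light rings under slowing treatment,
PFEs nearer and wider when slowed, farther and narrower when heated) and
are fully configurable per call. Treatment-series comparisons are made at a
snapshot within the signalling step of all compared individuals (t = 7.5
for the default two-ring train); after full settlement the slowed patterns
converge and the ordering of light-ring proportions is no longer
informative.

**Damage.** Damage hitting an organiser (circle covering the focus centre)
ablates it from the damage time: windows not yet open are cancelled, an
open window is truncated, units already released keep propagating. Hence
the timing law: ablation after all rears settle changes nothing; ablation
before the first release leaves bare background. The focal dot itself is
erased only if ablation struck before the first release — once signalling
has begun the dot's fate is sealed. Damage to empty space during the
signalling step seeds an ectopic organiser carrying a deliberately weak
stand-in train (one window, v₀ = half the host scenario's maximum, D = 1);
this default is a modelling placeholder, not a measured value.

## Rendering and measurement

Colour classes: background 0, focus 1, core 2 (inner and any extra rings),
light 3, outer 4, pfe 5, smb 6. Bands occupy half-open intervals
[rear, front); light rings are the gaps between consecutive eyespot dark
rings of the same train; the region inside the innermost ring's rear is
background (the light centre with a focal dot). At exact ties the
precedence is focus > core > outer > pfe > smb > light > background; whether
the focal dot should survive being overrun by the inner band is not
observationally settled, and this precedence (dot on top) is a documented
choice. The focus radius defaults to 1 cell-unit and is configurable.

A raster pixel takes the class of its centre point; profiles and rasters
are computed from the same resolved band extents, so they agree by
construction up to pixel quantisation. Ring metrics measured on rasters
carry an error of order the pixel size (the tests allow 2h); class pixel
areas converge on the analytic annulus areas as h shrinks.

Eyespot radius is the outer ring's front along the measured ray (falling
back to the outermost core ring when the outer band has fully collapsed or
been clamped away). Ring proportions are fractions of that radius for every
class inside it — focus, the inner background gap, core, light, outer — so
they sum to one. PFE distance is the band's rear edge (the part nearest the
focus); normalised PFE metrics divide by a reference individual, which
therefore measures exactly 1.00 against itself.

## Numerical choices

- Uniform fields use the closed form throughout; no integration error.
- Graded fields are integrated with fixed-step RK4 (default step 10⁻³
  time-units) on (x, v), with a hard stop once speed falls below 10⁻⁹
  cell-units/time-unit. For smooth fields the error is far below the
  rendering scale; across a discontinuous step in a(x) the crossing step
  limits accuracy to about 10⁻³ cell-units. Fields must be strictly
  negative everywhere; a field that is zero or positive anywhere queried is
  rejected rather than interpreted.
- First-contact times use `scipy.optimize.brentq` with xtol 10⁻¹⁰ after
  geometric bracket doubling.
- Angles for direction-dependent fields are resolved per ray; rasters under
  such fields sample 720 rays and assign each pixel its nearest ray
  (isotropic and barrier-only scenarios are evaluated exactly per pixel).
- All CSV/TSV/PGM output numbers are formatted with 10 significant digits,
  making repeated runs byte-identical.

## Preset parameterisations

The canonical two-ring train (v₀ = 10, a = −1, D = 3, I = 3, n = 2), the
PFE train (v₀ = 10, a = −1, D = 2) and the single-signal sweep values
(v₀ = 9…12 at a = −1) are fixed by the cases they reproduce. The
small-eyespot series is only qualitatively constrained (weaker organisers:
lower v₀, shorter D, longer I, shared start and snapshot t = 10), so the
package fixes one monotone series — v₀ = 10, 9.4, 8.8, 8.2; D = 3.0, 2.7,
2.4, 2.1; I = 3, 4, 5, 6, all at a = −1 — chosen so that at t = 10 no band
has fully converged (every ring width is positive) while the orderings
(strictly decreasing radius, strictly increasing light-ring proportion)
hold. The four organisers share the deceleration rate and are spaced 120
cell-units apart so they never interact. Similarly `graft_weakened`
(v₀ = 8, D = 2.2, I = 4.5) realises "weaker organiser" without a measured
magnitude, and `focus_only` uses v₀ = 1.5 so the final position (1.125)
stays within twice the focal radius.

## What the simulations do and do not show

All inputs are generated by the preset scenarios; no real wing images are
read or measured. The model is deterministic and noiseless: it emulates
ring geometry, its parameter dependence, and perturbation semantics, but
not scale-level texture, pigment chemistry, inter-individual variability,
or any molecular mechanism. In particular the reaction–diffusion layer that
presumably underlies the kinematics — self-enhancement, explicit inhibitory
signal concentrations, the dual-coloured proximal core — is out of scope:
inhibition enters only as clamps and thresholds (`min_gap`, `t_inhib`,
barriers). Passing tests therefore show that the kinematic description is
internally consistent and reproduces the documented structural rules and
perturbation orderings, not that real signals move ballistically.

## Known limitations

- Hard barrier clamps collapse a band to zero width once its rear reaches
  the barrier; a real pile-up would keep a visible compressed ring (the
  `soft` mode approximates this).
- Whether a clamped front's pile-up should push back on the band rear is
  unspecified; here the rear is clamped by the same barrier only when it
  reaches it.
- Ectopic organisers created by damage exist from their creation time, but
  rendering a scenario at times before an applied damage event treats the
  scenario description as given (the ectopic focus dot is drawn).
- Only uniform and table-based graded-radial fields are serialisable to
  the YAML schema; callable graded and directional fields are
  construct-in-code only.
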