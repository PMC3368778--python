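# ocellus

Kinematic simulation and analysis of butterfly eyespot and parafocal-element
colour patterns.

## The problem and who this is for

Butterfly eyespots are concentric ring patterns organised around a focus, a
small cluster of cells that releases morphogenic signals into the pupal wing
epithelium. In well-developed eyespots the inner black core ring is much
wider than the outer black ring (the *inside-wide rule*); small eyespots have
proportionally wider light rings; parafocal elements (PFEs) sit farther out
and narrow as they move; and physiological treatments (sodium tungstate,
cold shock, heat shock) shift all of these in characteristic directions.

`ocellus` is a simulator for the *kinematic* reading of these observations:
each dark ring is laid down by a signal that behaves as a uniformly
decelerated front. A signal released at time *s* with initial velocity *v₀*
into a medium of uniform resistance *a* < 0 sits at

    x(t) = v₀ τ + ½ a τ²,   τ = t − s,

until its velocity reaches zero at τ = −v₀/a, after which it stays at the
final position −v₀²/2a. A ring of finite width is the band produced by a
release *window* of duration *D*; a train of *n* windows separated by pauses
*I* builds a complete eyespot. Light rings are the blank spaces between dark
rings. The package is aimed at developmental biologists and modellers who
want to explore which ring structures, distortions and perturbation
responses this minimal kinematic model can and cannot produce.

What it does:

- closed-form and numerically integrated signal motion, including graded
  (position-dependent) and direction-dependent deceleration fields
  (`ocellus.kinematics`);
- release windows, signal trains, band extents and settlement
  (`ocellus.bands`);
- wing-surface scenarios with organisers, barriers, fusion/repulsion between
  elements, a minimum inter-ring gap, settlement by time-out or by velocity
  loss, physiological treatments and physical damage (`ocellus.scenario`);
- rendering to radial colour-class profiles and labelled rasters (PGM/PNG)
  (`ocellus.render`);
- ring-structure metrics: widths, proportions, the inside-wide flag, eyespot
  radius, PFE distance/width with reference normalisation
  (`ocellus.metrics`);
- a registry of named presets reproducing the canonical cases, plus
  parameter sweeps (`ocellus.presets`), YAML/JSON configs and a thin CLI
  (`ocellus.config`, `ocellus.cli`).

## Worked example

```python
import ocellus as oc

sc = oc.preset("figure6_typical").scenario   # v0=10, a=-1, D=3, I=3, n=2
m = oc.measure_rings(oc.radial_profile(sc, 10.0))
print(m.radius, m.core_width, m.light_width, m.outer_width, m.inside_wide)
```

prints

```
50.0 22.5 13.5 4.5 True
```

i.e. at the snapshot t = 10 the eyespot reaches radius 50 cell-units; the
core ring (22.5) is five times wider than the outer ring (4.5) — the
inside-wide configuration — with a 13.5-unit light ring between them. The
outer ring is narrow simply because its band travelled farther: both its
units converge on the same final position 50 = v₀²/2.

The `examples/` directory holds one short narrative script per capability
(single-signal kinematics, the typical eyespot, the small-eyespot series,
PFEs under treatments, interactions, damage semantics); each prints the
numbers it computes and says what they mean. The same functionality is
available from the shell:

```bash
ocellus presets list
ocellus simulate --preset figure6_typical --time 10 --out out/
ocellus sweep --param v0 --values 9,10,11,12 --preset figure5_sweep
ocellus measure --grid out/grid_t10.pgm --h 0.5
```

## Layout

- `src/ocellus/` — the library (see module list above)
- `examples/` — narrative example scripts
- `tests/` — pytest suite (unit, property and end-to-end acceptance tests)
- `docs/methods.md` — model description, parameter meanings, numerical
  choices and limitations
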