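"""Damage timing decides everything.

Ablating a focus only removes signals not yet released: damage after the
rings have settled is invisible, damage before any release erases the
eyespot, and damage to empty space while signalling is still under way
seeds an ectopic element.
"""

import numpy as np

import ocellus as oc
from ocellus.scenario import apply_damage

sc = oc.preset("figure6_typical").scenario

late = apply_damage(sc, 20.0, (0.0, 0.0), 2.0)
g0 = oc.render_grid(sc, 25.0, 0.5, 55.0)
g1 = oc.render_grid(late, 25.0, 0.5, 55.0)
print("ablation at t=20 (all settled): pattern identical ->",
      np.array_equal(g0.classes, g1.classes))

early = apply_damage(sc, 0.0, (0.0, 0.0), 2.0)
g2 = oc.render_grid(early, 10.0, 0.5, 55.0)
print("ablation at t=0 (nothing released): background only ->",
      set(np.unique(g2.classes)) == {oc.BACKGROUND})

mid = apply_damage(sc, 4.0, (0.0, 0.0), 2.0)
prof = oc.radial_profile(mid, 10.0)
classes = {c for c, _, _ in prof.segments}
print("ablation at t=4 (outer out, core not yet): outer ring only ->",
      oc.OUTER in classes and oc.CORE not in classes)

ectopic = apply_damage(sc, 2.0, (80.0, 0.0), 1.0)
print("damage to empty space at t=2: organisers now",
      len(ectopic.organisers), "(an ectopic element appears)")
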