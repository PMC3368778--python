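"""Inter-element interactions: barriers, fusion vs repulsion, minimum gap.

Expanding signals do not move in isolation: a nearby element can block
them (repulsive velocity loss), two organisers whose signals meet early
fuse into a double-focus eyespot, and inhibition keeps a minimum gap
open between the core and outer rings.
"""

from dataclasses import replace

import numpy as np

import ocellus as oc

# 1. a proximal line barrier 30 cell-units away distorts the eyespot
sc = oc.preset("ventral_barrier").scenario
for angle, side in [(0.0, "distal "), (np.pi, "proximal")]:
    m = oc.measure_rings(oc.radial_profile(sc, 10.0, angle))
    print(f"{side} radius at t=10: {m.radius:.1f}")

# 2. two foci 20 apart: fronts meet at t = 10 - sqrt(80) ~ 1.06
pair = oc.preset("double_focus").scenario
tc = oc.first_contact_time(pair, 0, 1)
print(f"\nfirst contact at t={tc:.3f}; "
      f"fused (t_inhib=5): {oc.fused_pairs(pair) == {(0, 1)}}")
repulsed = replace(pair, t_inhib=0.5)
front = [
    float(rb.front)
    for rb in oc.resolve_interactions(repulsed, 30.0, 0.0)
    if rb.organiser_index == 0 and rb.label == "outer"
][0]
print(f"with t_inhib=0.5 the fronts repulse and clamp at the midpoint: {front:g}")

# 3. minimum gap: with a short pause I=0.5 and g_min=3 the inner front
# is held exactly 3 cell-units behind the outer rear
gap = oc.preset("dorsal_min_gap").scenario
e = {rb.label: (float(rb.rear), float(rb.front))
     for rb in oc.resolve_interactions(gap, 12.0)}
print(f"\nouter rear {e['outer'][0]:g}, inner front {e['inner'][1]:g} "
      f"(gap = {e['outer'][0] - e['inner'][1]:g} = g_min)")
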