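"""The typical two-ring eyespot: outer ring first, core ring after a pause.

Two signals (v0=10, a=-1) are released for D=3 time-units each, separated
by a pause I=3.  Snapshots around t=9-10 show the classic inside-wide
eyespot: a wide inner core ring, a light ring, and a narrow outer ring.
"""

import ocellus as oc

p = oc.preset("figure6_typical")
print(p.doc, "\n")

for t in (1, 5, 9, 10, 12):
    prof = oc.radial_profile(p.scenario, float(t))
    m = oc.measure_rings(prof)
    print(
        f"t={t:>2}: radius {m.radius:5.1f}  core {m.core_width:5.2f}  "
        f"light {m.light_width:5.2f}  outer {m.outer_width:4.2f}  "
        f"inside-wide {m.inside_wide}"
    )

# At t=10 the core ring (22.5 cell-units) is five times wider than the
# outer ring (4.5): the outer signal narrowed because it travelled
# farther.  Write the raster to look at it:
grid = oc.render_grid(p.scenario, 10.0, h=0.5)
grid.to_pgm("typical_eyespot_t10.pgm")
print("\nwrote typical_eyespot_t10.pgm", grid.classes.shape)
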