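"""Small eyespots: weaker organisers give smaller, lighter-ringed eyespots.

Four organisers start signalling at t=0 with decreasing initial velocity
and release duration and an increasing pause before the second signal.
At the shared snapshot t=10 the eyespot radius shrinks down the series
while the light-ring share of the radius grows — the structural trend
that distinguishes minor from major eyespots.
"""

import ocellus as oc

sc = oc.preset("figure7_small_series").scenario
print("organiser   v0    D    I   radius  light-ring share")
for k, org in enumerate(sc.organisers):
    w = org.trains[0].windows[0]
    I = org.trains[0].intervals[0]
    m = oc.measure_rings(oc.radial_profile(sc, 10.0, organiser_index=k))
    print(
        f"{k:>9}  {w.v0:4.1f} {w.duration:4.1f} {I:4.1f}  "
        f"{m.radius:6.2f}  {m.proportions['light']:.3f}"
    )
# The radius column strictly decreases and the light-ring share strictly
# increases: small eyespots are proportionally dominated by their light
# ring, large ones by the dark core.
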