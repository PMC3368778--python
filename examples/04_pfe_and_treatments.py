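"""Parafocal elements and physiological treatments.

A PFE is a band from a single release window (v0=10, a=-1, D=2).  As it
travels out it narrows: distance from the focus grows while width
shrinks.  Treatments applied after release only change the propagation
rate — cold/tungstate slow it (the PFE stays near and wide), heat speeds
it (farther and narrower) — mirroring the treated-wing series.
"""

import ocellus as oc
from ocellus.scenario import apply_treatment

sc = oc.preset("figure8_pfe").scenario
print("untreated PFE band over time (normalised to the t=5 snapshot):")
tbl = oc.pfe_table(sc, [3.0, 5.0, 8.0, 11.0], reference_time=5.0)
print(tbl.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nsame wall-clock snapshot t=5, treatment applied at t=3:")
for label, treated in [
    ("cold ", apply_treatment(sc, "cold", 3.0)),
    ("none ", sc),
    ("heat ", apply_treatment(sc, "heat", 3.0)),
]:
    m = oc.measure_pfe(oc.radial_profile(treated, 5.0))
    print(f"  {label}: distance {m.distance:6.2f}  width {m.width:5.2f}")
# Reading down the list: slowed < untreated < accelerated in distance,
# and the nearer the PFE sits to the focus the wider it is.
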