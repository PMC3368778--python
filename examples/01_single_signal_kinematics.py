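"""A single decelerating signal: trajectory, stopping time, final position.

A morphogenic signal released with initial velocity v0 into a medium of
uniform resistance a < 0 follows x = v0*t + a*t^2/2 until its speed hits
zero, then stays put.  The final position v0^2/2|a| is what sets the
radius of the ring the signal will paint.
"""

import numpy as np

import ocellus as oc

for v0 in (9, 10, 11, 12):
    t_stop = oc.stopping_time(v0, -1.0)
    x_final = oc.final_position(v0, -1.0)
    print(f"v0={v0:>2}: stops at t={t_stop:g}, final position {x_final:g}")

# full trajectory of the v0=10 signal, sampled each time-unit
traj = oc.trajectory(oc.MotionParams(10.0), oc.UniformField(-1.0), np.arange(16.0))
print("\n t     x      v  stopped")
for t, x, v, s in zip(traj.t, traj.x, traj.v, traj.stopped):
    print(f"{t:4.0f} {x:6.2f} {v:6.2f}  {s}")

# Larger v0 -> farther final position (it grows with v0^2); after the
# stopping time the position column is exactly constant: the signal has
# settled and the ring radius is fixed.
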