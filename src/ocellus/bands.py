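"""Signal bands: release windows, timed trains, and settlement.

A dark ring is not a pulse: the organiser releases signal for a duration
``D``, producing a band of unit signals.  Every unit follows the same
decelerated motion but starts later than the one before it, so the band's
front (the first unit) stops first and the rear (the last unit) stops last
— the band narrows as it travels and finally collapses onto the common
final position.  A train stacks ``n`` such windows separated by pauses
``I``, which is how a two-ring eyespot (outer ring first, inner core ring
after a pause) or a multi-ring one arises from a single organiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InputError, NotYetReleasedError
from .kinematics import (
    STOP_SPEED,
    Field1D,
    GradedField,
    MotionParams,
    UniformField,
    position_and_velocity,
    stopping_time,
)

VALID_LABELS = ("outer", "inner", "pfe", "smb", "extra")


@dataclass(frozen=True)
class ReleaseWindow:
    """One release window: signal flows from the organiser on [start, end).

    ``label`` names the ring the window will paint (outer ring, inner core
    ring, parafocal element, submarginal band, or an extra ring of a
    multi-ring eyespot).
    """

    label: str
    start: float
    duration: float
    v0: float

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise InputError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}"
            )
        if self.duration <= 0:
            raise InputError(f"duration must be > 0, got {self.duration}")
        if self.start < 0:
            raise InputError(f"start must be >= 0, got {self.start}")
        if self.v0 < 0:
            raise InputError(f"v0 must be >= 0, got {self.v0}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class PropagationClock:
    """Piecewise time warp for signals already in flight.

    Physiological treatments change the propagation rate of released
    signals without touching their initial velocity: after an event
    ``(time, factor)`` the effective elapsed time accrues ``factor``
    time-units per wall-clock time-unit (factor < 1 slows propagation,
    factor > 1 speeds it).  Factors of successive events multiply.
    """

    events: tuple = ()

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if any(f <= 0 for _, f in self.events):
            raise InputError("propagation factors must be > 0")
        if times != sorted(times):
            raise InputError("clock events must be in time order")

    def rate_at(self, t: float) -> float:
        r = 1.0
        for e_time, factor in self.events:
            if e_time <= t:
                r *= factor
        return r

    def elapsed(self, release: float, t: float) -> float:
        """Effective elapsed propagation time from ``release`` to ``t``."""
        if t <= release:
            return 0.0
        total = 0.0
        cur = release
        for e_time, _ in self.events:
            if e_time <= cur:
                continue
            if e_time >= t:
                break
            total += self.rate_at(cur) * (e_time - cur)
            cur = e_time
        total += self.rate_at(cur) * (t - cur)
        return total

    def with_event(self, time: float, factor: float) -> "PropagationClock":
        return PropagationClock(tuple(sorted(self.events + ((time, factor),))))


IDENTITY_CLOCK = PropagationClock()


@dataclass(frozen=True)
class Band:
    """The moving annular signal produced by one release window.

    The band's extent at time ``t`` is the pair (rear, front): the front is
    the unit released when the window opened; the rear is the unit released
    at ``min(t, window end)`` — while the window is still open the rear sits
    at the focus, and the band renders as a filled disc.
    ``cutoff`` truncates the window early (organiser ablation mid-window).
    """

    window: ReleaseWindow
    field: Field1D
    clock: PropagationClock = IDENTITY_CLOCK
    cutoff: Optional[float] = None

    @property
    def rear_release(self) -> float:
        end = self.window.end
        if self.cutoff is not None:
            end = min(end, self.cutoff)
        return end

    def extent(self, t: float) -> tuple[float, float]:
        """(rear x, front x) at absolute time ``t``."""
        w = self.window
        if t < w.start:
            raise NotYetReleasedError(
                f"band window opens at t={w.start}, queried at t={t}"
            )
        params = MotionParams(w.v0, 0.0)
        tau_front = self.clock.elapsed(w.start, t)
        front, _ = position_and_velocity(params, self.field, tau_front)
        if t <= self.rear_release:
            rear = 0.0
        else:
            tau_rear = self.clock.elapsed(self.rear_release, t)
            rear, _ = position_and_velocity(params, self.field, tau_rear)
        return rear, front

    def width(self, t: float) -> float:
        rear, front = self.extent(t)
        return front - rear

    def is_settled(self, t: float) -> bool:
        """True iff both front and rear units have stopped moving."""
        w = self.window
        if t < w.start:
            raise NotYetReleasedError(
                f"band window opens at t={w.start}, queried at t={t}"
            )
        if t < self.rear_release and w.v0 > 0:
            return False
        params = MotionParams(w.v0, 0.0)
        tau_rear = self.clock.elapsed(self.rear_release, t)
        if isinstance(self.field, UniformField):
            return tau_rear >= stopping_time(w.v0, self.field.a) or w.v0 == 0
        _, v = position_and_velocity(params, self.field, tau_rear)
        return v <= STOP_SPEED


@dataclass(frozen=True)
class SignalTrain:
    """An ordered train of release windows from one organiser."""

    windows: tuple

    def __post_init__(self) -> None:
        if len(self.windows) < 1:
            raise InputError("a train needs at least one window")
        for prev, nxt in zip(self.windows, self.windows[1:]):
            if nxt.start < prev.end:
                raise InputError(
                    f"windows overlap: [{prev.start}, {prev.end}) and "
                    f"[{nxt.start}, {nxt.end})"
                )

    @property
    def n(self) -> int:
        return len(self.windows)

    @property
    def intervals(self) -> tuple:
        """Pauses between consecutive windows: next start minus previous end."""
        return tuple(
            nxt.start - prev.end for prev, nxt in zip(self.windows, self.windows[1:])
        )

    @property
    def max_v0(self) -> float:
        return max(w.v0 for w in self.windows)


def _default_labels(n: int) -> list[str]:
    if n == 1:
        return ["outer"]
    return ["outer", "inner"] + ["extra"] * (n - 2)


def build_train(
    start: float,
    v0_list: Union[float, Sequence[float]],
    D_list: Union[float, Sequence[float]],
    I_list: Union[float, Sequence[float], None] = None,
    labels: Optional[Sequence[str]] = None,
) -> SignalTrain:
    """Place ``n`` release windows sequentially from ``start``.

    Window k+1 opens at window k's end plus the pause ``I_list[k]``.
    Scalars broadcast: ``build_train(0, 10, 3, 3)`` with two durations is
    written ``build_train(0, [10, 10], [3, 3], [3])``.
    """
    D = [float(d) for d in np.atleast_1d(np.asarray(D_list, dtype=float))]
    n = len(D)
    v0 = np.broadcast_to(np.asarray(v0_list, dtype=float), (n,)).tolist()
    if I_list is None:
        I = [0.0] * (n - 1)
    else:
        I_arr = np.atleast_1d(np.asarray(I_list, dtype=float))
        if I_arr.size == 1 and n > 2:
            I_arr = np.broadcast_to(I_arr, (n - 1,))
        I = [float(i) for i in I_arr]
    if len(I) != max(n - 1, 0):
        raise InputError(
            f"need {n - 1} intervals for {n} windows, got {len(I)}"
        )
    if any(d <= 0 for d in D):
        raise InputError("all durations D must be > 0")
    if any(i < 0 for i in I):
        raise InputError("all intervals I must be >= 0")
    if labels is None:
        labels = _default_labels(n)
    if len(labels) != n:
        raise InputError(f"need {n} labels, got {len(labels)}")
    windows = []
    cursor = float(start)
    for k in range(n):
        windows.append(ReleaseWindow(labels[k], cursor, D[k], v0[k]))
        cursor += D[k]
        if k < n - 1:
            cursor += I[k]
    return SignalTrain(tuple(windows))
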