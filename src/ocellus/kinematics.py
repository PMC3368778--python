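"""Uniformly decelerated motion of a unit morphogenic signal.

A signal released at time ``s`` with initial speed ``v0`` into a medium of
constant resistance moves like a decelerating point: ``x = v0*(t-s) +
a*(t-s)**2 / 2`` with deceleration ``a < 0``.  Its speed reaches zero at the
stopping time ``-v0/a``, after which the position is clamped at the final
position ``-v0**2/(2*a)`` — the signal has settled and never moves again.
Position-dependent ("graded") resistance is supported by numerical
integration under the same clamping contract.

All distances are in abstract cell-units and times in time-units; the model
is dimensionless by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .errors import InputError, InvalidFieldError, NotYetReleasedError

#: speed below which an integrated signal is considered settled
STOP_SPEED = 1e-9
#: default RK4 step for graded-field integration (time-units)
DEFAULT_DT = 1e-3


@dataclass(frozen=True)
class MotionParams:
    """Release parameters of one unit signal.

    Parameters
    ----------
    v0
        Initial velocity in cell-units per time-unit; must be >= 0.
    release_time
        Time at which the unit leaves the organiser; must be finite, >= 0.
    """

    v0: float
    release_time: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v0) or self.v0 < 0:
            raise InputError(f"v0 must be finite and >= 0, got {self.v0}")
        if not np.isfinite(self.release_time) or self.release_time < 0:
            raise InputError(
                f"release_time must be finite and >= 0, got {self.release_time}"
            )


@dataclass(frozen=True)
class UniformField:
    """Constant deceleration ``a < 0`` everywhere."""

    a: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a >= 0:
            raise InvalidFieldError(f"deceleration must be < 0, got {self.a}")

    def along_ray(self, angle: float) -> "UniformField":
        return self

    def a_at(self, x: float) -> float:
        return self.a


@dataclass(frozen=True)
class GradedField:
    """Position-dependent deceleration ``a(x) < 0`` along one ray.

    ``a_of_x`` maps radial distance (cell-units) to a deceleration; it must
    be strictly negative on the whole domain ``[0, x_max]``.  Negativity is
    spot-checked on a fine grid at construction and enforced again at every
    integration step.
    """

    a_of_x: Callable[[float], float]
    x_max: float = 1e6
    _check_n: int = field(default=256, repr=False)

    def __post_init__(self) -> None:
        if self.x_max <= 0:
            raise InvalidFieldError("x_max must be > 0")
        xs = np.linspace(0.0, min(self.x_max, 1e4), self._check_n)
        for x in xs:
            a = self.a_of_x(float(x))
            if not np.isfinite(a) or a >= 0:
                raise InvalidFieldError(
                    f"deceleration must be < 0 everywhere; a({x:g}) = {a:g}"
                )

    def along_ray(self, angle: float) -> "GradedField":
        return self

    def a_at(self, x: float) -> float:
        a = self.a_of_x(float(x))
        if not np.isfinite(a) or a >= 0:
            raise InvalidFieldError(
                f"deceleration must be < 0 everywhere; a({x:g}) = {a:g}"
            )
        return a


@dataclass(frozen=True)
class DirectionalField:
    """A deceleration field that differs per ray direction.

    ``field_of_angle`` maps an angle in radians to the 1-D field
    (uniform or graded) along that ray.
    """

    field_of_angle: Callable[[float], Union[UniformField, GradedField]]

    def along_ray(self, angle: float):
        f = self.field_of_angle(float(angle))
        if not isinstance(f, (UniformField, GradedField)):
            raise InvalidFieldError(
                f"field_of_angle must return a 1-D field, got {type(f).__name__}"
            )
        return f


Field1D = Union[UniformField, GradedField]
DecelerationField = Union[UniformField, GradedField, DirectionalField]


def stopping_time(v0: float, a: float) -> float:
    """Time after release at which a uniformly decelerated signal stops.

    Solves dx/dt = v0 + a*t = 0, giving ``-v0/a``.
    """
    if a >= 0 or not np.isfinite(a):
        raise InvalidFieldError(f"deceleration must be < 0, got {a}")
    if v0 < 0:
        raise InputError(f"v0 must be >= 0, got {v0}")
    return -v0 / a


def final_position(v0: float, a: float) -> float:
    """Settled position of a uniformly decelerated signal: ``-v0**2/(2a)``."""
    if a >= 0 or not np.isfinite(a):
        raise InvalidFieldError(f"deceleration must be < 0, got {a}")
    if v0 < 0:
        raise InputError(f"v0 must be >= 0, got {v0}")
    return -(v0 * v0) / (2.0 * a)


def _uniform_position(v0: float, a: float, tau) -> np.ndarray:
    """Clamped quadratic x(tau) for elapsed time(s) tau >= 0."""
    tau = np.asarray(tau, dtype=float)
    t_stop = -v0 / a
    # return the settled position exactly (bit-identical to final_position)
    # once stopped, rather than the rounded quadratic at t_stop
    return np.where(
        tau >= t_stop, -(v0 * v0) / (2.0 * a), v0 * tau + 0.5 * a * tau * tau
    )


def _uniform_velocity(v0: float, a: float, tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    t_stop = -v0 / a
    return np.where(tau >= t_stop, 0.0, v0 + a * tau)


def _integrate_graded(
    v0: float, field: GradedField, tau_targets: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """RK4-integrate dx/dt = v, dv/dt = a(x) to each elapsed time in
    ``tau_targets`` (sorted ascending).  Returns (x, v) at the targets,
    with v clamped to 0 (and x frozen) once speed drops below STOP_SPEED.
    """

    def accel(x: float) -> float:
        return field.a_at(min(x, field.x_max))

    x, v, tau = 0.0, float(v0), 0.0
    out_x = np.empty_like(tau_targets)
    out_v = np.empty_like(tau_targets)
    stopped = v0 <= STOP_SPEED
    for i, target in enumerate(tau_targets):
        while not stopped and tau < target:
            h = min(dt, target - tau)
            k1x, k1v = v, accel(x)
            k2x, k2v = v + 0.5 * h * k1v, accel(x + 0.5 * h * k1x)
            k3x, k3v = v + 0.5 * h * k2v, accel(x + 0.5 * h * k2x)
            k4x, k4v = v + h * k3v, accel(x + h * k3x)
            x += (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
            v += (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
            tau += h
            if v <= STOP_SPEED:
                v = 0.0
                stopped = True
        out_x[i], out_v[i] = x, v
    return out_x, out_v


def position_at(
    params: MotionParams,
    field: Field1D,
    t: float,
    *,
    dt: float = DEFAULT_DT,
) -> float:
    """Radial position of a unit signal at absolute time ``t``.

    Uniform fields use the closed form with clamping at the final position;
    graded fields are integrated numerically under the same contract.
    Raises :class:`NotYetReleasedError` for ``t`` before the release time.
    """
    x, _ = position_and_velocity(params, field, t, dt=dt)
    return x


def position_and_velocity(
    params: MotionParams,
    field: Field1D,
    t: float,
    *,
    dt: float = DEFAULT_DT,
) -> tuple[float, float]:
    """Position and velocity at absolute time ``t`` (see :func:`position_at`)."""
    if t < params.release_time:
        raise NotYetReleasedError(
            f"signal released at t={params.release_time} queried at t={t}"
        )
    tau = t - params.release_time
    if isinstance(field, UniformField):
        x = float(_uniform_position(params.v0, field.a, tau))
        v = float(_uniform_velocity(params.v0, field.a, tau))
        return x, v
    if isinstance(field, GradedField):
        xs, vs = _integrate_graded(params.v0, field, np.array([tau]), dt)
        return float(xs[0]), float(vs[0])
    raise InvalidFieldError(
        f"position_at needs a 1-D field along one ray, got {type(field).__name__}"
    )


@dataclass
class Trajectory:
    """Sampled (t, x, v) motion of one unit signal."""

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray

    @property
    def stopped(self) -> np.ndarray:
        """0/1 flag per sample: has the signal settled?"""
        return (self.v <= STOP_SPEED).astype(int)

    def to_tsv(self, path_or_buf) -> None:
        """Write columns t, x, v, stopped as tab-separated text."""
        buf = io.StringIO()
        buf.write("t\tx\tv\tstopped\n")
        for t, x, v, s in zip(self.t, self.x, self.v, self.stopped):
            buf.write(f"{t:.10g}\t{x:.10g}\t{v:.10g}\t{s:d}\n")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(buf.getvalue())
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(buf.getvalue())


def trajectory(
    params: MotionParams,
    field: Field1D,
    t_grid: Sequence[float],
    *,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Sample the motion on an ascending time grid.

    All grid times must be >= the release time; the samples are
    non-decreasing in x and exactly constant after settlement.
    """
    t_arr = np.asarray(t_grid, dtype=float)
    if t_arr.ndim != 1 or t_arr.size == 0:
        raise InputError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t_arr) < 0):
        raise InputError("t_grid must be sorted ascending")
    if t_arr[0] < params.release_time:
        raise NotYetReleasedError(
            f"t_grid starts at {t_arr[0]} before release at {params.release_time}"
        )
    tau = t_arr - params.release_time
    if isinstance(field, UniformField):
        x = _uniform_position(params.v0, field.a, tau)
        v = _uniform_velocity(params.v0, field.a, tau)
    elif isinstance(field, GradedField):
        x, v = _integrate_graded(params.v0, field, tau, dt)
    else:
        raise InvalidFieldError(
            f"trajectory needs a 1-D field along one ray, got {type(field).__name__}"
        )
    return Trajectory(t=t_arr, x=np.asarray(x), v=np.asarray(v))
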