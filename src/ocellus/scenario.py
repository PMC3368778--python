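"""Wing-surface scenarios: organisers, barriers, treatments, damage, interactions.

A scenario assembles everything needed to run the model on one wing
surface: organising centres with their signal trains, the deceleration
field of the medium, barriers that repulse expanding signals, the minimum
gap inhibition keeps open between consecutive dark rings, the settlement
mode (run until every signal stops, or freeze the snapshot when the
signalling step times out), and the perturbations an experimenter applies
— physiological treatments (tungstate / cold shock slow the signalling
step, heat shock accelerates it) and physical damage (focal ablation or
ectopic-element induction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .bands import Band, PropagationClock, ReleaseWindow, SignalTrain, build_train
from .errors import InputError
from .kinematics import (
    DecelerationField,
    DirectionalField,
    GradedField,
    UniformField,
    final_position,
    stopping_time,
)

TREATMENT_KINDS = ("tungstate", "cold", "heat")

#: default scaling factors for signals not yet released when a slowing
#: treatment (tungstate / cold shock) is applied: initial velocity and
#: duration shrink, the pause before the window stretches.  Heat shock
#: uses the reciprocals.  The propagation factor applies to signals
#: already in flight.
SLOW_FACTORS = {"k_v": 0.6, "k_D": 0.6, "k_I": 1.5, "k_prop": 0.6}


@dataclass(frozen=True)
class Treatment:
    kind: str
    time: float
    k_v: float
    k_D: float
    k_I: float
    k_prop: float


@dataclass(frozen=True)
class Organiser:
    """An organising centre (prospective eyespot focus) on the wing plane."""

    position: tuple
    trains: tuple
    focus_radius: float = 1.0
    ablation_time: Optional[float] = None
    clocks: Optional[tuple] = None  # parallel to trains/windows; None = identity

    def __post_init__(self) -> None:
        if self.focus_radius < 0:
            raise InputError(f"focus_radius must be >= 0, got {self.focus_radius}")

    @property
    def active(self) -> bool:
        return self.ablation_time is None

    def clock_for(self, train_idx: int, window_idx: int) -> PropagationClock:
        if self.clocks is None:
            return PropagationClock()
        return self.clocks[train_idx][window_idx]

    @property
    def max_v0(self) -> float:
        return max((w.v0 for tr in self.trains for w in tr.windows), default=0.0)


@dataclass(frozen=True)
class LineBarrier:
    """A line element in the plane that blocks signal propagation.

    The line passes through ``point`` with unit ``normal``; a signal front
    travelling along a ray is clamped where the ray crosses the line.
    ``mode='soft'`` decelerates the front smoothly within ``margin``
    cell-units of the line instead of clamping it hard.
    """

    point: tuple
    normal: tuple
    mode: str = "hard"
    margin: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise InputError(f"barrier mode must be hard|soft, got {self.mode!r}")
        n = math.hypot(*self.normal)
        if n == 0:
            raise InputError("barrier normal must be non-zero")

    def distance_along_ray(self, origin: Sequence[float], angle) -> np.ndarray:
        """Distance from ``origin`` along direction ``angle`` to the line;
        +inf where the ray never reaches it."""
        angle = np.asarray(angle, dtype=float)
        nx, ny = self.normal
        norm = math.hypot(nx, ny)
        nx, ny = nx / norm, ny / norm
        px, py = self.point
        ox, oy = origin
        # orient the normal away from the origin so "reaching the line"
        # means travelling in the +normal direction
        side = (px - ox) * nx + (py - oy) * ny
        if side < 0:
            nx, ny, side = -nx, -ny, -side
        if side <= 0:
            raise InputError("barrier line passes through the origin")
        u_dot_n = np.cos(angle) * nx + np.sin(angle) * ny
        with np.errstate(divide="ignore"):
            d = np.where(u_dot_n > 1e-12, side / np.maximum(u_dot_n, 1e-300), np.inf)
        return d


@dataclass(frozen=True)
class RayBarrier:
    """Barrier given directly as a radial clamp distance per ray angle."""

    distance_of_angle: object  # callable(angle)->distance, vectorised or not
    mode: str = "hard"
    margin: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise InputError(f"barrier mode must be hard|soft, got {self.mode!r}")

    def distance_along_ray(self, origin: Sequence[float], angle) -> np.ndarray:
        angle = np.asarray(angle, dtype=float)
        f = self.distance_of_angle
        try:
            d = np.asarray(f(angle), dtype=float)
        except (TypeError, ValueError):
            d = np.asarray([f(a) for a in np.atleast_1d(angle)], dtype=float)
            d = d.reshape(angle.shape)
        if np.any(d <= 0):
            raise InputError("barrier distance must be > 0 where defined")
        return np.broadcast_to(d, angle.shape)


Barrier = Union[LineBarrier, RayBarrier]


@dataclass(frozen=True)
class Settlement:
    """How the pattern is fixed: 'run_to_settlement' lets every signal stop
    on its own; 'time_out' freezes the snapshot at t_out when the
    signalling step ends."""

    mode: str = "run_to_settlement"
    t_out: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("run_to_settlement", "time_out"):
            raise InputError(
                f"settlement mode must be run_to_settlement|time_out, got {self.mode!r}"
            )
        if self.mode == "time_out" and (self.t_out is None or self.t_out <= 0):
            raise InputError("time_out mode requires t_out > 0")

    def effective_time(self, t: float) -> float:
        if self.mode == "time_out":
            return min(t, self.t_out)
        return t


@dataclass(frozen=True)
class DamageEvent:
    time: float
    location: tuple
    radius: float


@dataclass(frozen=True)
class Scenario:
    """A runnable wing-surface description."""

    organisers: tuple
    field: DecelerationField = UniformField(-1.0)
    barriers: tuple = ()
    min_gap: float = 0.0
    settlement: Settlement = Settlement()
    t_inhib: float = 0.0
    damage_events: tuple = ()
    treatments: tuple = ()

    def __post_init__(self) -> None:
        if self.min_gap < 0:
            raise InputError(f"min_gap must be >= 0, got {self.min_gap}")
        if self.t_inhib < 0:
            raise InputError(f"t_inhib must be >= 0, got {self.t_inhib}")

    def domain_radius(self) -> float:
        """A radius safely containing every settled pattern (for rendering)."""
        r = 10.0
        for org in self.organisers:
            reach = 0.0
            if isinstance(self.field, UniformField):
                reach = max(
                    (final_position(w.v0, self.field.a)
                     for tr in org.trains for w in tr.windows),
                    default=0.0,
                )
            else:  # conservative bound: field must be at least as steep somewhere
                reach = max(
                    (w.v0 * stopping_time(w.v0, -0.01)
                     for tr in org.trains for w in tr.windows),
                    default=0.0,
                )
            r = max(r, math.hypot(*org.position) + reach + org.focus_radius)
        return r * 1.05


@dataclass
class ResolvedBand:
    """Effective (clamped) extent of one band along the queried ray(s)."""

    organiser_index: int
    train_index: int
    window_index: int
    label: str
    rear: np.ndarray  # same shape as the queried angle
    front: np.ndarray
    fused_with: frozenset = frozenset()


# ---------------------------------------------------------------------------
# treatments


def _treatment_factors(kind: str, factors: Optional[dict]) -> Treatment:
    if kind not in TREATMENT_KINDS:
        raise InputError(
            f"unknown treatment kind {kind!r}; valid: {TREATMENT_KINDS}"
        )
    base = dict(SLOW_FACTORS)
    if kind == "heat":
        base = {k: 1.0 / v for k, v in base.items()}
    if factors:
        for k, v in factors.items():
            if k not in base:
                raise InputError(f"unknown treatment factor {k!r}")
            if v <= 0:
                raise InputError(f"treatment factor {k} must be > 0, got {v}")
            base[k] = float(v)
    return base


def _rescale_train(
    train: SignalTrain,
    clocks: tuple,
    t_treat: float,
    fac: dict,
) -> tuple[SignalTrain, tuple]:
    """Split a train at the treatment time: released windows keep their
    parameters and gain a propagation-rate event; unreleased windows are
    re-parameterised (v0*k_v, D*k_D, preceding pause * k_I) and re-placed
    sequentially, never earlier than the treatment time."""
    new_windows: list[ReleaseWindow] = []
    new_clocks: list[PropagationClock] = []
    intervals = train.intervals
    prev_end = None
    for k, w in enumerate(train.windows):
        if w.start < t_treat:  # already released: warp propagation only
            new_windows.append(w)
            new_clocks.append(clocks[k].with_event(t_treat, fac["k_prop"]))
            prev_end = w.end
        else:
            pause = intervals[k - 1] if k > 0 else None
            if prev_end is None:
                start = max(w.start, t_treat)
            else:
                start = max(prev_end + fac["k_I"] * (pause if pause is not None else 0.0),
                            t_treat)
            nw = ReleaseWindow(w.label, start, w.duration * fac["k_D"], w.v0 * fac["k_v"])
            new_windows.append(nw)
            new_clocks.append(clocks[k])
            prev_end = nw.end
    return SignalTrain(tuple(new_windows)), tuple(new_clocks)


def apply_treatment(
    scenario: Scenario,
    kind: str,
    time: float,
    factors: Optional[dict] = None,
) -> Scenario:
    """Apply a physiological treatment at ``time``.

    Signals not yet released are re-parameterised (v0, D scaled by k_v,
    k_D; the pause before each window by k_I); signals already in flight
    keep their initial velocity and only their propagation rate changes
    (factor k_prop).  Defaults: tungstate/cold 0.6 / 0.6 / 1.5 / 0.6, heat
    the reciprocals.
    """
    if time < 0:
        raise InputError(f"treatment time must be >= 0, got {time}")
    fac = _treatment_factors(kind, factors)
    new_orgs = []
    for org in scenario.organisers:
        clocks = org.clocks or tuple(
            tuple(PropagationClock() for _ in tr.windows) for tr in org.trains
        )
        new_trains, new_clocks = [], []
        for tr, cl in zip(org.trains, clocks):
            ntr, ncl = _rescale_train(tr, cl, time, fac)
            new_trains.append(ntr)
            new_clocks.append(ncl)
        new_orgs.append(
            replace(org, trains=tuple(new_trains), clocks=tuple(new_clocks))
        )
    rec = Treatment(kind, time, fac["k_v"], fac["k_D"], fac["k_I"], fac["k_prop"])
    return replace(
        scenario,
        organisers=tuple(new_orgs),
        treatments=scenario.treatments + (rec,),
    )


# ---------------------------------------------------------------------------
# damage


def _default_ectopic_train(scenario: Scenario, time: float) -> SignalTrain:
    """Stand-in train for a damage-induced ectopic organiser: one window,
    half the host scenario's strongest initial velocity, duration 1."""
    vmax = max((org.max_v0 for org in scenario.organisers), default=2.0)
    return build_train(time, 0.5 * vmax, 1.0)


def apply_damage(
    scenario: Scenario, time: float, location: Sequence[float], radius: float
) -> Scenario:
    """Physical damage at ``location`` with the given radius.

    Hitting an organiser ablates it from ``time`` on: windows not yet
    opened are cancelled, units already released keep propagating.  Damage
    to empty space during the signalling step seeds an ectopic organiser
    with a weak default train.
    """
    if radius < 0:
        raise InputError(f"damage radius must be >= 0, got {radius}")
    if time < 0:
        raise InputError(f"damage time must be >= 0, got {time}")
    loc = (float(location[0]), float(location[1]))
    hit = False
    new_orgs = []
    for org in scenario.organisers:
        d = math.hypot(org.position[0] - loc[0], org.position[1] - loc[1])
        if d <= radius + org.focus_radius:
            hit = True
            abl = time if org.ablation_time is None else min(org.ablation_time, time)
            new_orgs.append(replace(org, ablation_time=abl))
        else:
            new_orgs.append(org)
    event = DamageEvent(time, loc, radius)
    if not hit:
        within_step = (
            scenario.settlement.mode != "time_out"
            or time < scenario.settlement.t_out
        )
        if within_step:
            new_orgs.append(
                Organiser(
                    position=loc,
                    trains=(_default_ectopic_train(scenario, time),),
                    focus_radius=new_orgs[0].focus_radius if new_orgs else 1.0,
                )
            )
    return replace(
        scenario,
        organisers=tuple(new_orgs),
        damage_events=scenario.damage_events + (event,),
    )


# ---------------------------------------------------------------------------
# interactions


def _live_bands(scenario: Scenario, org_idx: int, t: float, angle: float):
    """Bands of one organiser whose windows have opened by time t,
    honouring ablation (cancelled / truncated windows)."""
    org = scenario.organisers[org_idx]
    field1d = scenario.field.along_ray(angle)
    out = []
    for ti, tr in enumerate(org.trains):
        for wi, w in enumerate(tr.windows):
            if w.start > t:
                continue
            if org.ablation_time is not None and w.start >= org.ablation_time:
                continue
            cutoff = None
            if org.ablation_time is not None and org.ablation_time < w.end:
                cutoff = org.ablation_time
            out.append(
                (
                    ti,
                    wi,
                    Band(w, field1d, clock=org.clock_for(ti, wi), cutoff=cutoff),
                )
            )
    return out


def _front_of(scenario: Scenario, org_idx: int, t: float) -> float:
    """Outermost front of one organiser at time t (0 before any release)."""
    t_eff = scenario.settlement.effective_time(t)
    bands = _live_bands(scenario, org_idx, t_eff, 0.0)
    if not bands:
        return 0.0
    return max(b.extent(t_eff)[1] for _, _, b in bands)


def first_contact_time(
    scenario: Scenario, i: int, j: int, t_max: float = 1e4
) -> Optional[float]:
    """Earliest time at which the expanding fronts of organisers i and j
    meet, found by bracketing + root-finding on the analytic fronts;
    None if they never touch."""
    oi, oj = scenario.organisers[i], scenario.organisers[j]
    d = math.hypot(
        oi.position[0] - oj.position[0], oi.position[1] - oj.position[1]
    )
    if d <= 0:
        return 0.0

    def gap(t: float) -> float:
        return _front_of(scenario, i, t) + _front_of(scenario, j, t) - d

    starts = [w.start for org in (oi, oj) for tr in org.trains for w in tr.windows]
    if not starts:
        return None
    t_lo = min(starts)
    # latest time anything can still move (generous bound)
    t_hi = t_lo + 1.0
    while gap(t_hi) < 0 and t_hi < t_max:
        t_hi *= 2.0
    if gap(t_hi) < 0:
        return None
    if gap(t_lo) >= 0:
        return t_lo
    return float(brentq(gap, t_lo, t_hi, xtol=1e-10))


def fused_pairs(scenario: Scenario) -> set:
    """Organiser index pairs whose bands met before inhibition matured
    (first contact earlier than t_inhib) and therefore fused."""
    out = set()
    n = len(scenario.organisers)
    for i in range(n):
        for j in range(i + 1, n):
            tc = first_contact_time(scenario, i, j)
            if tc is not None and tc < scenario.t_inhib:
                out.add((i, j))
    return out


def _soft_clamp(front: np.ndarray, dist: np.ndarray, margin: float) -> np.ndarray:
    """Smooth repulsion: identity up to (dist - margin), then an
    exponential approach that never reaches the barrier."""
    inner = dist - margin
    over = np.maximum(front - inner, 0.0)
    soft = inner + margin * (1.0 - np.exp(-over / margin))
    return np.where(front > inner, np.minimum(front, soft), front)


def _apply_barrier(rear, front, dist, mode: str, margin: float):
    if mode == "hard":
        return np.minimum(rear, dist), np.minimum(front, dist)
    return np.minimum(rear, dist), _soft_clamp(front, dist, margin)


def resolve_interactions(
    scenario: Scenario, t: float, angle=0.0, organiser_index: Optional[int] = None
) -> list[ResolvedBand]:
    """Effective band extents at time ``t`` along the queried ray angle(s).

    Applies, in order: the settlement time-out; barrier clamps (the rear is
    clamped by the same barrier only once it reaches it); repulsion between
    non-fused organisers in contact (each front clamped at the
    perpendicular bisector, i.e. the mutual midpoint along the joining
    line); and the minimum-gap clamp keeping each inner front at least
    ``min_gap`` behind the next outer band's rear.  Fused organiser pairs
    (first contact before ``t_inhib``) are left unclamped so their
    occupancies union.
    """
    angle_arr = np.atleast_1d(np.asarray(angle, dtype=float))
    scalar = np.isscalar(angle) or np.asarray(angle).ndim == 0
    t_eff = scenario.settlement.effective_time(t)
    fused = fused_pairs(scenario) if len(scenario.organisers) > 1 else set()

    resolved: list[ResolvedBand] = []
    for oi, org in enumerate(scenario.organisers):
        if organiser_index is not None and oi != organiser_index:
            continue
        is_directional = isinstance(scenario.field, DirectionalField)
        triples = []
        if is_directional:
            rear = np.empty_like(angle_arr)
            front = np.empty_like(angle_arr)
            # evaluate per ray; directional fields need a loop
            first = _live_bands(scenario, oi, t_eff, float(angle_arr.flat[0]))
            for bi in range(len(first)):
                r = np.empty_like(angle_arr)
                f = np.empty_like(angle_arr)
                for k, a in enumerate(angle_arr.flat):
                    blist = _live_bands(scenario, oi, t_eff, float(a))
                    rr, ff = blist[bi][2].extent(t_eff)
                    r.flat[k], f.flat[k] = rr, ff
                ti, wi, band = first[bi]
                triples.append((ti, wi, band, r, f))
        else:
            for ti, wi, band in _live_bands(scenario, oi, t_eff, 0.0):
                rr, ff = band.extent(t_eff)
                triples.append(
                    (
                        ti,
                        wi,
                        band,
                        np.full_like(angle_arr, rr),
                        np.full_like(angle_arr, ff),
                    )
                )

        partners = [
            j
            for j in range(len(scenario.organisers))
            if j != oi and (min(oi, j), max(oi, j)) not in fused
        ]
        fused_with = frozenset(
            j
            for j in range(len(scenario.organisers))
            if j != oi and (min(oi, j), max(oi, j)) in fused
        )

        clamp_dists = []
        for barrier in scenario.barriers:
            clamp_dists.append(
                (
                    barrier.distance_along_ray(org.position, angle_arr),
                    barrier.mode,
                    barrier.margin,
                )
            )
        for j in partners:
            other = scenario.organisers[j]
            tc = first_contact_time(scenario, oi, j)
            if tc is None or t_eff < tc:
                continue  # repulsion engages only once fronts meet
            dx = other.position[0] - org.position[0]
            dy = other.position[1] - org.position[1]
            bisector = LineBarrier(
                point=(org.position[0] + dx / 2.0, org.position[1] + dy / 2.0),
                normal=(dx, dy),
            )
            clamp_dists.append(
                (bisector.distance_along_ray(org.position, angle_arr), "hard", 0.0)
            )

        clamped = []
        for ti, wi, band, rear, front in triples:
            for dist, mode, margin in clamp_dists:
                rear, front = _apply_barrier(rear, front, dist, mode, margin)
            clamped.append((ti, wi, band, rear, front))

        # minimum-gap clamp, cascading outermost-first within each train
        by_train: dict[int, list] = {}
        for item in clamped:
            by_train.setdefault(item[0], []).append(item)
        for ti, items in by_train.items():
            items.sort(key=lambda it: it[2].window.start)
            for k in range(1, len(items)):
                outer_rear = items[k - 1][3]
                ti_k, wi_k, band_k, rear_k, front_k = items[k]
                # inhibition halts the whole inner band at the gap limit:
                # units piling up there clamp both front and rear
                limit = np.maximum(outer_rear - scenario.min_gap, 0.0)
                new_front = np.minimum(front_k, limit)
                new_rear = np.minimum(rear_k, new_front)
                items[k] = (ti_k, wi_k, band_k, new_rear, new_front)
            for ti_k, wi_k, band_k, rear_k, front_k in items:
                resolved.append(
                    ResolvedBand(
                        organiser_index=oi,
                        train_index=ti_k,
                        window_index=wi_k,
                        label=band_k.window.label,
                        rear=rear_k[0] if scalar else rear_k,
                        front=front_k[0] if scalar else front_k,
                        fused_with=fused_with,
                    )
                )
    return resolved
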