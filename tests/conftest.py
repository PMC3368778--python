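"""Shared fixtures and the independent fine-step motion oracle."""

import numpy as np
import pytest

import ocellus as oc


def oracle_position(v0: float, a: float, tau: float, dt: float = 1e-4) -> float:
    """Brute-force kinematic stepper, independent of the closed form.

    Advances x += v*h + a*h^2/2, v += a*h in steps of at most ``dt``;
    when a step would drive the speed negative it shortens the step to
    land exactly on the stop, then freezes.
    """
    x, v, t = 0.0, float(v0), 0.0
    while t < tau and v > 0.0:
        h = min(dt, tau - t)
        if v + a * h < 0.0:
            h = min(h, v / (-a))
        x += v * h + 0.5 * a * h * h
        v += a * h
        t += h
        if v <= 0.0:
            break
    return x


def bisect_contact(front_fn, d: float, t_lo: float, t_hi: float, iters: int = 80):
    """Bisection oracle for the first time two expanding fronts span d."""
    lo, hi = t_lo, t_hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if front_fn(mid) >= d:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@pytest.fixture
def oracle():
    return oracle_position


@pytest.fixture
def typical_eyespot():
    """Two-ring eyespot scenario: v0=10, a=-1, D=3, I=3, n=2."""
    return oc.preset("figure6_typical").scenario


@pytest.fixture
def pfe_scenario():
    """Single parafocal-element band: v0=10, a=-1, D=2."""
    return oc.preset("figure8_pfe").scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20120313)
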