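"""Quantification of ring patterns.

Measures what a colour-pattern analysis of a real wing would measure:
ring widths along a ray, their proportions of the eyespot radius, whether
the inside-wide rule holds (inner core ring wider than the outer ring),
and for parafocal elements the focus-to-element distance and element
width, optionally normalised against an untreated reference individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError
from .render import (
    BACKGROUND,
    CORE,
    FOCUS,
    LIGHT,
    OUTER,
    PFE,
    PatternGrid,
    RadialProfile,
    radial_profile,
)


@dataclass
class RingMetrics:
    """Measured widths and proportions of one eyespot along one ray.

    ``radius`` is the outer ring's front edge; proportions are fractions
    of the radius for every class inside it (focus, the background gap
    between focus and core, core, light, outer) and sum to 1.
    """

    focus_width: float = 0.0
    inner_gap_width: float = 0.0
    core_width: float = 0.0
    light_width: float = 0.0
    outer_width: float = 0.0
    radius: float = 0.0
    proportions: dict = dc_field(default_factory=dict)
    inside_wide: bool = False


@dataclass
class PFEMetrics:
    """Distance (focus centre to the nearest edge) and width of a PFE."""

    distance: float
    width: float
    norm_distance: Optional[float] = None
    norm_width: Optional[float] = None


def _segments_from_grid(grid: PatternGrid, angle: float):
    """Approximate (class, start, end) segments by sampling pixels along a
    ray at half-pixel steps."""
    r, cls = grid.ray_classes(angle)
    if len(r) == 0:
        return [], grid.h / 2.0
    step = r[1] - r[0] if len(r) > 1 else grid.h / 2.0
    segments = []
    start = 0.0
    cur = cls[0]
    for k in range(1, len(cls)):
        if cls[k] != cur:
            edge = (r[k] + r[k - 1]) / 2.0
            segments.append((int(cur), start, edge))
            start, cur = edge, cls[k]
    segments.append((int(cur), start, r[-1] + step / 2.0))
    return segments, step


def measure_rings(
    pattern: Union[RadialProfile, PatternGrid], ray: float = 0.0
) -> RingMetrics:
    """Ring widths, proportions, radius and the inside-wide flag.

    Accepts an analytic radial profile (exact) or a rendered grid (widths
    then carry pixel-quantisation error of order the pixel size).  A
    pattern with no eyespot dark ring yields all-zero metrics with
    ``inside_wide`` False rather than an error.
    """
    if isinstance(pattern, PatternGrid):
        segments, _ = _segments_from_grid(pattern, ray)
    else:
        segments = pattern.segments

    def total(cls):
        return sum(e - s for c, s, e in segments if c == cls)

    outer_end = max((e for c, s, e in segments if c == OUTER), default=0.0)
    if outer_end == 0.0:
        # no outer ring: fall back to the outermost dark (core) ring, if any
        outer_end = max((e for c, s, e in segments if c == CORE), default=0.0)
    if outer_end == 0.0:
        return RingMetrics()
    inside = [(c, s, min(e, outer_end)) for c, s, e in segments if s < outer_end]

    def total_inside(cls):
        return sum(e - s for c, s, e in inside if c == cls)

    m = RingMetrics(
        focus_width=total_inside(FOCUS),
        inner_gap_width=total_inside(BACKGROUND),
        core_width=total_inside(CORE),
        light_width=total_inside(LIGHT),
        outer_width=total_inside(OUTER),
        radius=outer_end,
    )
    m.proportions = {
        "focus": m.focus_width / m.radius,
        "inner_gap": m.inner_gap_width / m.radius,
        "core": m.core_width / m.radius,
        "light": m.light_width / m.radius,
        "outer": m.outer_width / m.radius,
    }
    m.inside_wide = m.core_width > m.outer_width
    return m


def measure_pfe(
    profile: RadialProfile, reference: Optional[PFEMetrics] = None
) -> PFEMetrics:
    """Distance and width of the PFE band on a profile.

    ``distance`` is the rear (focus-near) edge of the band — the nearest
    part of the element to the focus centre.  With a ``reference``, the
    normalised values are the ratios to the reference individual, so the
    reference measured against itself gives exactly (1.0, 1.0).
    """
    pfe_segments = [(s, e) for c, s, e in profile.segments if c == PFE]
    if len(pfe_segments) != 1:
        raise InputError(
            f"expected exactly one PFE band on the ray, found {len(pfe_segments)}"
        )
    start, end = pfe_segments[0]
    m = PFEMetrics(distance=start, width=end - start)
    if reference is not None:
        if reference.width <= 0 or reference.distance <= 0:
            raise NormalizationError(
                "reference PFE has zero distance or width; cannot normalise"
            )
        m.norm_distance = m.distance / reference.distance
        m.norm_width = m.width / reference.width
    return m


def metrics_table(
    scenario,
    times,
    angle: float = 0.0,
    organiser_index: int = 0,
) -> pd.DataFrame:
    """One row of ring metrics per snapshot time (CSV-ready)."""
    rows = []
    for t in times:
        prof = radial_profile(
            scenario, t, angle, organiser_index=organiser_index
        )
        m = measure_rings(prof, angle)
        rows.append(
            {
                "t": t,
                "ray": angle,
                "focus_width": m.focus_width,
                "inner_gap_width": m.inner_gap_width,
                "core_width": m.core_width,
                "light_width": m.light_width,
                "outer_width": m.outer_width,
                "radius": m.radius,
                "light_proportion": m.proportions.get("light", 0.0),
                "inside_wide": m.inside_wide,
            }
        )
    return pd.DataFrame(rows)


def pfe_table(
    scenario,
    times,
    angle: float = 0.0,
    organiser_index: int = 0,
    reference_time: Optional[float] = None,
) -> pd.DataFrame:
    """One row of PFE metrics per snapshot time, optionally normalised
    against the measurement at ``reference_time``."""
    ref = None
    if reference_time is not None:
        ref = measure_pfe(
            radial_profile(
                scenario, reference_time, angle, organiser_index=organiser_index
            )
        )
    rows = []
    for t in times:
        prof = radial_profile(scenario, t, angle, organiser_index=organiser_index)
        m = measure_pfe(prof, ref)
        rows.append(
            {
                "t": t,
                "ray": angle,
                "distance": m.distance,
                "width": m.width,
                "norm_distance": m.norm_distance,
                "norm_width": m.norm_width,
            }
        )
    return pd.DataFrame(rows)
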