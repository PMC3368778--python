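"""Rendering: band extents -> radial colour-class profiles and 2D rasters.

The model assigns signals only to dark rings; light rings are the blank
spaces left between them.  A snapshot at time ``t`` is turned into a
radial profile (ordered colour-class segments along one ray) or a labelled
raster on a square pixel grid centred on the first organiser.

Colour classes: 0 background, 1 focus, 2 core (inner dark ring, including
the extra rings of multi-ring eyespots), 3 light ring, 4 outer dark ring,
5 parafocal element, 6 submarginal band.  At exact ties the precedence is
focus > core > outer > pfe > smb > light > background; bands occupy
half-open intervals [rear, front).  When the inner band's rear has left
the origin, the region inside it is background again (the light centre
with a focal dot seen in real eyespots).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError
from .kinematics import DirectionalField
from .scenario import ResolvedBand, Scenario, resolve_interactions

BACKGROUND, FOCUS, CORE, LIGHT, OUTER, PFE, SMB = range(7)

CLASS_NAMES = {
    BACKGROUND: "background",
    FOCUS: "focus",
    CORE: "core",
    LIGHT: "light",
    OUTER: "outer",
    PFE: "pfe",
    SMB: "smb",
}

#: ring-label -> raster class; 'inner' and 'extra' windows both paint core-dark
LABEL_CLASS = {"outer": OUTER, "inner": CORE, "extra": CORE, "pfe": PFE, "smb": SMB}

EYESPOT_LABELS = ("outer", "inner", "extra")

#: painting order: later classes overwrite earlier ones at ties
_PRECEDENCE_LOW_TO_HIGH = (LIGHT, SMB, PFE, OUTER, CORE, FOCUS)

#: fixed palette for optional PNG export (RGB)
PALETTE = {
    BACKGROUND: (235, 224, 192),
    FOCUS: (250, 250, 250),
    CORE: (30, 30, 30),
    LIGHT: (238, 201, 88),
    OUTER: (30, 30, 30),
    PFE: (80, 60, 40),
    SMB: (120, 100, 70),
}


@dataclass
class RadialProfile:
    """Ordered colour-class segments along one ray from an organiser.

    ``segments`` is a list of (class, start r, end r) covering [0, r_max]
    contiguously without overlap.
    """

    angle: float
    segments: list
    r_max: float

    def class_at(self, r: float) -> int:
        for cls, start, end in self.segments:
            if start <= r < end:
                return cls
        return BACKGROUND

    def total_width(self, cls: int) -> float:
        return sum(end - start for c, start, end in self.segments if c == cls)

    def boundaries(self) -> list:
        return [seg[1] for seg in self.segments] + [self.segments[-1][2]]


def _organiser_intervals(
    scenario: Scenario, resolved: list, org_idx: int, t: float
):
    """Candidate (class, start, end) intervals for one organiser from its
    resolved band extents, including the focus dot and light gaps."""
    org = scenario.organisers[org_idx]
    intervals = []
    eyespot = []
    for rb in resolved:
        if rb.organiser_index != org_idx:
            continue
        rear = float(np.asarray(rb.rear).reshape(-1)[0])
        front = float(np.asarray(rb.front).reshape(-1)[0])
        if front <= rear:
            continue
        cls = LABEL_CLASS[rb.label]
        intervals.append((cls, rear, front))
        if rb.label in EYESPOT_LABELS:
            eyespot.append((rear, front))
    # light rings: gaps between consecutive eyespot dark rings
    eyespot.sort()
    for (r0, f0), (r1, f1) in zip(eyespot, eyespot[1:]):
        if r1 > f0:
            intervals.append((LIGHT, f0, r1))
    if org.focus_radius > 0 and _focus_visible(org):
        intervals.append((FOCUS, 0.0, org.focus_radius))
    return intervals


def _focus_visible(org) -> bool:
    """The focal dot's fate is sealed once signalling has begun: ablation
    erases it only if it struck before the first release."""
    if org.ablation_time is None:
        return True
    first_start = min(
        (w.start for tr in org.trains for w in tr.windows), default=0.0
    )
    return org.ablation_time > first_start


def _assemble_segments(intervals: list, r_max: float) -> list:
    """Resolve overlapping candidate intervals into contiguous segments by
    class precedence."""
    pts = sorted({0.0, r_max} | {p for _, s, e in intervals for p in (s, e) if 0 <= p <= r_max})
    prec = {cls: rank for rank, cls in enumerate(_PRECEDENCE_LOW_TO_HIGH, start=1)}
    prec[BACKGROUND] = 0
    segments = []
    for lo, hi in zip(pts, pts[1:]):
        if hi <= lo:
            continue
        best = BACKGROUND
        for cls, s, e in intervals:
            if s <= lo and hi <= e and prec[cls] > prec[best]:
                best = cls
        if segments and segments[-1][0] == best:
            segments[-1] = (best, segments[-1][1], hi)
        else:
            segments.append((best, lo, hi))
    if not segments:
        segments = [(BACKGROUND, 0.0, r_max)]
    return segments


def radial_profile(
    scenario: Scenario,
    t: float,
    angle: float = 0.0,
    *,
    organiser_index: int = 0,
    r_max: Optional[float] = None,
) -> RadialProfile:
    """Colour-class profile along one ray from an organiser's centre.

    The profile covers [0, r_max] contiguously: focus dot, dark rings at
    their clamped band extents, light rings in the gaps between eyespot
    rings, background elsewhere.
    """
    if t < 0:
        raise InputError(f"t must be >= 0, got {t}")
    if r_max is None:
        r_max = scenario.domain_radius()
    if not scenario.organisers:
        return RadialProfile(angle, [(BACKGROUND, 0.0, r_max)], r_max)
    t_eff = scenario.settlement.effective_time(t)
    resolved = resolve_interactions(
        scenario, t, float(angle), organiser_index=organiser_index
    )
    intervals = _organiser_intervals(scenario, resolved, organiser_index, t_eff)
    return RadialProfile(angle, _assemble_segments(intervals, r_max), r_max)


@dataclass
class PatternGrid:
    """Labelled square raster of colour classes.

    ``classes[iy, ix]`` holds the class of the pixel whose centre is at
    ``origin + (-extent + (ix + 0.5) h, -extent + (iy + 0.5) h)``; the
    origin is the first organiser's position.
    """

    classes: np.ndarray
    h: float
    origin: tuple
    extent: float

    def pixel_centres(self):
        n = self.classes.shape[0]
        coords = -self.extent + (np.arange(n) + 0.5) * self.h
        return coords + self.origin[0], coords + self.origin[1]

    def class_at_point(self, x: float, y: float) -> int:
        ix = int(np.floor((x - self.origin[0] + self.extent) / self.h))
        iy = int(np.floor((y - self.origin[1] + self.extent) / self.h))
        n = self.classes.shape[0]
        if not (0 <= ix < n and 0 <= iy < n):
            return BACKGROUND
        return int(self.classes[iy, ix])

    def ray_classes(self, angle: float, step: Optional[float] = None):
        """Sample pixel classes outward from the origin along a ray;
        returns (r samples, classes)."""
        if step is None:
            step = self.h / 2.0
        r = np.arange(step / 2.0, self.extent, step)
        xs = self.origin[0] + r * np.cos(angle)
        ys = self.origin[1] + r * np.sin(angle)
        cls = np.array([self.class_at_point(x, y) for x, y in zip(xs, ys)])
        return r, cls

    def class_area(self, cls: int) -> float:
        return float(np.sum(self.classes == cls)) * self.h * self.h

    def to_pgm(self, path, binary: bool = False) -> None:
        """Write the raster as PGM (P2 plain text by default, P5 binary)."""
        n = self.classes.shape[0]
        if binary:
            header = f"P5\n{n} {n}\n255\n".encode()
            with open(path, "wb") as fh:
                fh.write(header)
                fh.write(self.classes.astype(np.uint8).tobytes())
        else:
            lines = [f"P2", f"{n} {n}", "255"]
            for row in self.classes:
                lines.append(" ".join(str(int(v)) for v in row))
            with open(path, "w") as fh:
                fh.write("\n".join(lines) + "\n")

    def to_png(self, path) -> None:
        """Write an RGB PNG with the fixed class palette."""
        from PIL import Image

        rgb = np.zeros(self.classes.shape + (3,), dtype=np.uint8)
        for cls, colour in PALETTE.items():
            rgb[self.classes == cls] = colour
        Image.fromarray(rgb[::-1], "RGB").save(path)


def read_pgm(path) -> np.ndarray:
    """Read a P2 (plain) or P5 (binary) PGM raster of class integers."""
    with open(path, "rb") as fh:
        data = fh.read()
    tokens = []
    i = 0
    while len(tokens) < 4 and i < len(data):
        # tokenise header, skipping comments
        while i < len(data) and data[i : i + 1].isspace():
            i += 1
        if data[i : i + 1] == b"#":
            while i < len(data) and data[i : i + 1] != b"\n":
                i += 1
            continue
        j = i
        while j < len(data) and not data[j : j + 1].isspace():
            j += 1
        tokens.append(data[i:j])
        i = j
    if tokens[0] not in (b"P2", b"P5"):
        raise InputError(f"not a PGM file: magic {tokens[0]!r}")
    w, h = int(tokens[1]), int(tokens[2])
    if tokens[0] == b"P5":
        raster = np.frombuffer(data[i + 1 : i + 1 + w * h], dtype=np.uint8)
    else:
        raster = np.array(data[i:].split(), dtype=int)
    return raster.reshape(h, w)


def _paint_organiser(
    scenario: Scenario,
    t: float,
    org_idx: int,
    r: np.ndarray,
    theta: np.ndarray,
    out: np.ndarray,
    n_rays: int = 720,
) -> None:
    """Paint one organiser's classes onto ``out`` (same shape as r/theta),
    overwriting lower-precedence classes only."""
    org = scenario.organisers[org_idx]
    t_eff = scenario.settlement.effective_time(t)
    if isinstance(scenario.field, DirectionalField):
        ray_angles = np.linspace(-np.pi, np.pi, n_rays, endpoint=False)
        resolved = resolve_interactions(
            scenario, t, ray_angles, organiser_index=org_idx
        )
        idx = np.round((theta + np.pi) / (2 * np.pi / n_rays)).astype(int) % n_rays
        def band_arrays(rb):
            return np.asarray(rb.rear)[idx], np.asarray(rb.front)[idx]
    else:
        resolved = resolve_interactions(
            scenario, t, theta.ravel(), organiser_index=org_idx
        )
        def band_arrays(rb):
            return (
                np.asarray(rb.rear).reshape(theta.shape),
                np.asarray(rb.front).reshape(theta.shape),
            )

    eyespot_bands = []
    masks = {cls: np.zeros(r.shape, dtype=bool) for cls in CLASS_NAMES}
    for rb in resolved:
        rear, front = band_arrays(rb)
        cls = LABEL_CLASS[rb.label]
        masks[cls] |= (r >= rear) & (r < front)
        if rb.label in EYESPOT_LABELS:
            eyespot_bands.append((rb.window_index, rb.train_index, rear, front))
    # light: gaps between consecutive eyespot rings of the same train
    by_train: dict = {}
    for wi, ti, rear, front in eyespot_bands:
        by_train.setdefault(ti, []).append((wi, rear, front))
    for ti, items in by_train.items():
        items.sort(key=lambda it: it[0])
        for (_, rear0, _), (_, _, front1) in zip(items, items[1:]):
            masks[LIGHT] |= (r >= front1) & (r < rear0)
    if org.focus_radius > 0 and _focus_visible(org):
        masks[FOCUS] |= r < org.focus_radius

    prec = {cls: rank for rank, cls in enumerate(_PRECEDENCE_LOW_TO_HIGH, start=1)}
    prec[BACKGROUND] = 0
    prec_lut = np.zeros(len(CLASS_NAMES), dtype=np.int8)
    for cls, rank in prec.items():
        prec_lut[cls] = rank
    prec_map = prec_lut[out]
    for cls in _PRECEDENCE_LOW_TO_HIGH:
        m = masks[cls] & (prec_map < prec[cls])
        out[m] = cls
        prec_map[m] = prec[cls]


def render_grid(
    scenario: Scenario,
    t: float,
    h: float,
    extent: Optional[float] = None,
) -> PatternGrid:
    """Rasterise the pattern at time ``t`` on pixels of size ``h``.

    Each pixel takes the class of its centre point; with several
    organisers, classes combine across them with the tie precedence
    focus > core > outer > pfe > smb > light > background.  Deterministic
    for fixed inputs.
    """
    if h <= 0:
        raise InputError(f"grid pixel size h must be > 0, got {h}")
    if t < 0:
        raise InputError(f"t must be >= 0, got {t}")
    if extent is None:
        extent = scenario.domain_radius()
    origin = scenario.organisers[0].position if scenario.organisers else (0.0, 0.0)
    n = max(int(np.ceil(2.0 * extent / h)), 1)
    coords = -extent + (np.arange(n) + 0.5) * h
    X, Y = np.meshgrid(coords + origin[0], coords + origin[1])
    out = np.zeros((n, n), dtype=np.int16)
    for oi, org in enumerate(scenario.organisers):
        dx = X - org.position[0]
        dy = Y - org.position[1]
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        _paint_organiser(scenario, t, oi, r, theta, out)
    return PatternGrid(classes=out, h=h, origin=tuple(origin), extent=float(extent))
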