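"""Named scenario presets: the canonical worked examples of the model.

Each preset is a fully specified wing-surface scenario reproducing one of
the standard cases the model is built to explain: the single-signal t-x
sweep, the typical two-ring eyespot, the small-eyespot series, the
parafocal-element train, the atypical eyespots (blank-core, focus-only,
multi-ring, fused double focus), the graft-weakened organiser, damage
semantics, and the minimum-gap / barrier distortion cases.  Presets double
as the deterministic fixture generators for the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .bands import SignalTrain, build_train
from .errors import InputError
from .kinematics import UniformField, final_position
from .metrics import measure_rings
from .render import radial_profile
from .scenario import (
    LineBarrier,
    Organiser,
    Scenario,
    Settlement,
    apply_damage,
)


@dataclass(frozen=True)
class Preset:
    name: str
    scenario: Scenario
    snapshot_times: tuple
    doc: str


def _single_organiser(train: SignalTrain, **kw) -> Scenario:
    return Scenario(
        organisers=(Organiser(position=(0.0, 0.0), trains=(train,)),),
        field=UniformField(-1.0),
        **kw,
    )


def _figure5_sweep() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, 1.0))
    return Preset(
        "figure5_sweep",
        sc,
        tuple(range(0, 16)),
        "Single-signal t-x base case (v0=10, a=-1) for parameter sweeps of "
        "the decelerated-motion curve.",
    )


def _figure6_typical() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, [3.0, 3.0], [3.0]))
    return Preset(
        "figure6_typical",
        sc,
        tuple(range(1, 13)),
        "Typical two-ring eyespot: two signals, v0=10, a=-1, D=3, I=3; the "
        "inside-wide configuration appears around t=9-10.",
    )


#: small-eyespot series: weaker organisers have lower initial velocity,
#: shorter release duration, and a longer pause before the second signal
SMALL_SERIES_V0 = (10.0, 9.4, 8.8, 8.2)
SMALL_SERIES_D = (3.0, 2.7, 2.4, 2.1)
SMALL_SERIES_I = (3.0, 4.0, 5.0, 6.0)
_SMALL_SERIES_SPACING = 120.0


def _figure7_small_series() -> Preset:
    orgs = []
    for k, (v0, D, I) in enumerate(
        zip(SMALL_SERIES_V0, SMALL_SERIES_D, SMALL_SERIES_I)
    ):
        orgs.append(
            Organiser(
                position=(0.0, k * _SMALL_SERIES_SPACING),
                trains=(build_train(0.0, v0, [D, D], [I]),),
            )
        )
    sc = Scenario(organisers=tuple(orgs), field=UniformField(-1.0))
    return Preset(
        "figure7_small_series",
        sc,
        (10.0,),
        "Four eyespots of decreasing organiser activity (decreasing v0 and "
        "D, increasing I), all starting at t=0, snapshot at t=10: radii "
        "shrink while light-ring proportions grow.",
    )


def _figure8_pfe() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, 2.0, labels=["pfe"]))
    return Preset(
        "figure8_pfe",
        sc,
        (3.0, 5.0, 8.0, 11.0),
        "Parafocal-element band: one release window, v0=10, a=-1, D=2; the "
        "band narrows as it travels outward.",
    )


def _blank_core() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, 3.0))
    return Preset(
        "blank_core",
        sc,
        (10.0,),
        "Blank-core eyespot: the inner signal is never released (n=1), so "
        "there is no core ring.",
    )


def _focus_only() -> Preset:
    sc = _single_organiser(build_train(0.0, 1.5, 3.0))
    return Preset(
        "focus_only",
        sc,
        (10.0,),
        "Focus-only eyespot: initial velocity so low that the signal's final "
        "position stays within twice the focal radius.",
    )


def _multi_ring() -> Preset:
    sc = _single_organiser(
        build_train(0.0, 10.0, [2.0, 2.0, 2.0], [2.0, 2.0])
    )
    return Preset(
        "multi_ring",
        sc,
        (12.0,),
        "Multi-ring eyespot: the organiser cycles three release windows "
        "(n=3), giving three dark rings.",
    )


def _double_focus() -> Preset:
    train_a = build_train(0.0, 10.0, [3.0, 3.0], [3.0])
    train_b = build_train(0.0, 10.0, [3.0, 3.0], [3.0])
    sc = Scenario(
        organisers=(
            Organiser(position=(0.0, 0.0), trains=(train_a,)),
            Organiser(position=(20.0, 0.0), trains=(train_b,)),
        ),
        field=UniformField(-1.0),
        t_inhib=5.0,
    )
    return Preset(
        "double_focus",
        sc,
        (10.0,),
        "Double-focus eyespot: two organisers 20 cell-units apart whose "
        "bands meet before inhibition matures (t_inhib=5), so they fuse.",
    )


def _graft_weakened() -> Preset:
    sc = _single_organiser(build_train(0.0, 8.0, [2.2, 2.2], [4.5]))
    return Preset(
        "graft_weakened",
        sc,
        (10.0,),
        "Graft-weakened organiser: lower initial velocity, shorter release "
        "duration and a longer pause, giving a smaller eyespot with a "
        "proportionally wider light ring.",
    )


def _hindwing_damage() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, [3.0, 3.0], [3.0]))
    sc = apply_damage(sc, 20.0, (0.0, 0.0), 2.0)
    return Preset(
        "hindwing_damage",
        sc,
        (10.0, 25.0),
        "Focal damage applied only after every signal has settled (t=20): "
        "the pattern is insensitive to it because the rings were already "
        "in flight or settled when the focus was destroyed.",
    )


def _dorsal_min_gap() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, [3.0, 3.0], [0.5]))
    sc = replace(sc, min_gap=3.0)
    return Preset(
        "dorsal_min_gap",
        sc,
        (12.0,),
        "Short pause between the two signals with an active minimum gap "
        "(g_min=3): the inner front is held 3 cell-units behind the outer "
        "rear, producing the narrow constant light ring.",
    )


def _ventral_barrier() -> Preset:
    sc = _single_organiser(build_train(0.0, 10.0, [3.0, 3.0], [3.0]))
    barrier = LineBarrier(point=(-30.0, 0.0), normal=(1.0, 0.0))
    sc = replace(sc, barriers=(barrier,))
    return Preset(
        "ventral_barrier",
        sc,
        (10.0,),
        "A proximal line element blocks signal propagation at 30 cell-units "
        "on the proximal side, compressing the eyespot there while the "
        "distal side expands freely.",
    )


_REGISTRY = {
    p.__name__[1:]: p
    for p in (
        _figure5_sweep,
        _figure6_typical,
        _figure7_small_series,
        _figure8_pfe,
        _blank_core,
        _focus_only,
        _multi_ring,
        _double_focus,
        _graft_weakened,
        _hindwing_damage,
        _dorsal_min_gap,
        _ventral_barrier,
    )
}


def preset_names() -> list:
    return sorted(_REGISTRY)


def preset(name: str) -> Preset:
    """Look up a named preset; unknown names list the valid registry."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; valid names: {', '.join(preset_names())}"
        ) from None


# ---------------------------------------------------------------------------
# parameter sweeps

SWEEPABLE = ("v0", "a", "D", "I", "T_out")


def _with_parameter(scenario: Scenario, parameter: str, value: float) -> Scenario:
    if parameter == "a":
        return replace(scenario, field=UniformField(float(value)))
    if parameter == "T_out":
        return replace(
            scenario, settlement=Settlement(mode="time_out", t_out=float(value))
        )
    new_orgs = []
    for org in scenario.organisers:
        new_trains = []
        for tr in org.trains:
            labels = [w.label for w in tr.windows]
            v0s = [w.v0 for w in tr.windows]
            Ds = [w.duration for w in tr.windows]
            Is = list(tr.intervals)
            if parameter == "v0":
                v0s = [float(value)] * len(v0s)
            elif parameter == "D":
                Ds = [float(value)] * len(Ds)
            elif parameter == "I":
                Is = [float(value)] * len(Is)
            new_trains.append(
                build_train(tr.windows[0].start, v0s, Ds, Is or None, labels)
            )
        new_orgs.append(replace(org, trains=tuple(new_trains)))
    return replace(scenario, organisers=tuple(new_orgs))


SWEEP_COLUMNS = [
    "value",
    "final_position",
    "radius",
    "core_width",
    "light_width",
    "outer_width",
    "light_proportion",
    "inside_wide",
]


def sweep(
    parameter: str,
    values: Sequence[float],
    base_preset: Union[str, Preset],
) -> pd.DataFrame:
    """Vary one structural determinant and tabulate the outcome.

    For each value the base preset is re-parameterised (all windows /
    intervals set to the value for v0, D, I; the uniform deceleration for
    a; the signalling time-out for T_out), run to its last snapshot time,
    and measured: the free final position of the first signal, the eyespot
    radius and ring widths along the ray angle 0.
    """
    if parameter not in SWEEPABLE:
        raise InputError(
            f"unknown sweep parameter {parameter!r}; valid: {SWEEPABLE}"
        )
    p = preset(base_preset) if isinstance(base_preset, str) else base_preset
    t_snap = max(p.snapshot_times)
    rows = []
    for value in values:
        sc = _with_parameter(p.scenario, parameter, float(value))
        first_window = sc.organisers[0].trains[0].windows[0]
        a = sc.field.a if isinstance(sc.field, UniformField) else None
        fp = final_position(first_window.v0, a) if a is not None else np.nan
        prof = radial_profile(sc, t_snap, 0.0)
        m = measure_rings(prof)
        rows.append(
            {
                "value": float(value),
                "final_position": fp,
                "radius": m.radius,
                "core_width": m.core_width,
                "light_width": m.light_width,
                "outer_width": m.outer_width,
                "light_proportion": m.proportions.get("light", 0.0),
                "inside_wide": m.inside_wide,
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
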