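"""Config parsing, validation and deterministic output writing.

Scenarios and run configs are plain YAML/JSON mappings.  Scenario schema::

    organisers:
      - x: 0.0
        y: 0.0
        focus_radius: 1.0
        trains:
          - start: 0.0
            signals: [{label: outer, v0: 10.0, D: 3.0}, ...]
            intervals: [3.0]
    field: {kind: uniform, a: -1.0}        # or {kind: graded-radial, table: [[x, a], ...]}
    barriers: [{type: line, point: [x, y], normal: [nx, ny], mode: hard, margin: 2.0}]
    min_gap: 0.0
    settlement: {mode: run_to_settlement}  # or {mode: time_out, t_out: 10.0}
    t_inhib: 0.0
    treatments: []                          # records of applied treatments
    damage: []                              # records of applied damage events

Numbers in every CSV/TSV/PGM output are formatted with 10 significant
digits so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import yaml

from .bands import PropagationClock, ReleaseWindow, SignalTrain
from .errors import InputError, ValidationError
from .kinematics import GradedField, MotionParams, UniformField, trajectory
from .metrics import measure_rings
from .render import CLASS_NAMES, radial_profile, render_grid
from .scenario import (
    DamageEvent,
    LineBarrier,
    Organiser,
    RayBarrier,
    Scenario,
    Settlement,
    Treatment,
)

log = logging.getLogger("ocellus")


def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".10g")


# ---------------------------------------------------------------------------
# scenario <-> dict


def scenario_to_dict(sc: Scenario) -> dict:
    """Serialise a scenario to the plain-mapping schema."""
    orgs = []
    for org in sc.organisers:
        trains = []
        for tr in org.trains:
            trains.append(
                {
                    "start": tr.windows[0].start,
                    "signals": [
                        {"label": w.label, "v0": w.v0, "D": w.duration}
                        for w in tr.windows
                    ],
                    "intervals": list(tr.intervals),
                }
            )
        d = {
            "x": org.position[0],
            "y": org.position[1],
            "focus_radius": org.focus_radius,
            "trains": trains,
        }
        if org.ablation_time is not None:
            d["ablation_time"] = org.ablation_time
        if org.clocks is not None:
            d["clocks"] = [
                [[list(e) for e in cl.events] for cl in tcl] for tcl in org.clocks
            ]
        orgs.append(d)
    if isinstance(sc.field, UniformField):
        field = {"kind": "uniform", "a": sc.field.a}
    elif isinstance(sc.field, GradedField) and hasattr(sc.field.a_of_x, "table"):
        field = {"kind": "graded-radial", "table": sc.field.a_of_x.table}
    else:
        raise ValidationError(
            "field: only uniform and table-based graded-radial fields are "
            "serialisable"
        )
    barriers = []
    for b in sc.barriers:
        if isinstance(b, LineBarrier):
            barriers.append(
                {
                    "type": "line",
                    "point": list(b.point),
                    "normal": list(b.normal),
                    "mode": b.mode,
                    "margin": b.margin,
                }
            )
        else:
            raise ValidationError(
                "barriers: only line barriers are serialisable"
            )
    settlement = {"mode": sc.settlement.mode}
    if sc.settlement.t_out is not None:
        settlement["t_out"] = sc.settlement.t_out
    return {
        "organisers": orgs,
        "field": field,
        "barriers": barriers,
        "min_gap": sc.min_gap,
        "settlement": settlement,
        "t_inhib": sc.t_inhib,
        "treatments": [
            {
                "kind": tr.kind,
                "time": tr.time,
                "k_v": tr.k_v,
                "k_D": tr.k_D,
                "k_I": tr.k_I,
                "k_prop": tr.k_prop,
            }
            for tr in sc.treatments
        ],
        "damage": [
            {"time": d.time, "location": list(d.location), "radius": d.radius}
            for d in sc.damage_events
        ],
    }


class _TableInterp:
    """Piecewise-linear a(x) from a [[x, a], ...] table (kept for re-dump)."""

    def __init__(self, table):
        self.table = [[float(x), float(a)] for x, a in table]
        arr = np.asarray(self.table, dtype=float)
        self._x = arr[:, 0]
        self._a = arr[:, 1]

    def __call__(self, x: float) -> float:
        return float(np.interp(x, self._x, self._a))


def _need(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ValidationError(f"{path}.{key}: required field missing")
    return mapping[key]


def scenario_from_dict(d: dict) -> Scenario:
    """Build a scenario from the plain-mapping schema, validating field by
    field (error messages name the offending path)."""
    if not isinstance(d, dict):
        raise ValidationError("scenario: expected a mapping")
    orgs = []
    for i, od in enumerate(d.get("organisers", [])):
        path = f"organisers[{i}]"
        x = float(_need(od, "x", path))
        y = float(_need(od, "y", path))
        trains = []
        for j, td in enumerate(od.get("trains", [])):
            tpath = f"{path}.trains[{j}]"
            start = float(td.get("start", 0.0))
            signals = _need(td, "signals", tpath)
            intervals = [float(v) for v in td.get("intervals", [])]
            if len(intervals) != max(len(signals) - 1, 0):
                raise ValidationError(
                    f"{tpath}.intervals: need {len(signals) - 1} values, "
                    f"got {len(intervals)}"
                )
            windows = []
            cursor = start
            for k, sd in enumerate(signals):
                spath = f"{tpath}.signals[{k}]"
                try:
                    w = ReleaseWindow(
                        _need(sd, "label", spath),
                        cursor,
                        float(_need(sd, "D", spath)),
                        float(_need(sd, "v0", spath)),
                    )
                except InputError as exc:
                    raise ValidationError(f"{spath}: {exc}") from None
                windows.append(w)
                cursor = w.end + (intervals[k] if k < len(intervals) else 0.0)
            trains.append(SignalTrain(tuple(windows)))
        clocks = None
        if "clocks" in od:
            clocks = tuple(
                tuple(
                    PropagationClock(tuple((float(t), float(f)) for t, f in cl))
                    for cl in tcl
                )
                for tcl in od["clocks"]
            )
        orgs.append(
            Organiser(
                position=(x, y),
                trains=tuple(trains),
                focus_radius=float(od.get("focus_radius", 1.0)),
                ablation_time=(
                    float(od["ablation_time"]) if "ablation_time" in od else None
                ),
                clocks=clocks,
            )
        )
    fd = d.get("field", {"kind": "uniform", "a": -1.0})
    kind = fd.get("kind", "uniform")
    if kind == "uniform":
        field = UniformField(float(_need(fd, "a", "field")))
    elif kind == "graded-radial":
        table = _need(fd, "table", "field")
        interp = _TableInterp(table)
        field = GradedField(interp, x_max=interp.table[-1][0])
    else:
        raise ValidationError(f"field.kind: unknown kind {kind!r}")
    barriers = []
    for i, bd in enumerate(d.get("barriers", [])):
        bpath = f"barriers[{i}]"
        if bd.get("type", "line") != "line":
            raise ValidationError(f"{bpath}.type: only 'line' is supported")
        barriers.append(
            LineBarrier(
                point=tuple(float(v) for v in _need(bd, "point", bpath)),
                normal=tuple(float(v) for v in _need(bd, "normal", bpath)),
                mode=bd.get("mode", "hard"),
                margin=float(bd.get("margin", 2.0)),
            )
        )
    sd = d.get("settlement", {"mode": "run_to_settlement"})
    try:
        settlement = Settlement(
            mode=sd.get("mode", "run_to_settlement"),
            t_out=float(sd["t_out"]) if "t_out" in sd else None,
        )
    except InputError as exc:
        raise ValidationError(f"settlement: {exc}") from None
    treatments = tuple(
        Treatment(
            td["kind"], float(td["time"]), float(td["k_v"]),
            float(td["k_D"]), float(td["k_I"]), float(td["k_prop"]),
        )
        for td in d.get("treatments", [])
    )
    damage = tuple(
        DamageEvent(
            float(dd["time"]),
            tuple(float(v) for v in dd["location"]),
            float(dd["radius"]),
        )
        for dd in d.get("damage", [])
    )
    try:
        return Scenario(
            organisers=tuple(orgs),
            field=field,
            barriers=tuple(barriers),
            min_gap=float(d.get("min_gap", 0.0)),
            settlement=settlement,
            t_inhib=float(d.get("t_inhib", 0.0)),
            treatments=treatments,
            damage_events=damage,
        )
    except InputError as exc:
        raise ValidationError(str(exc)) from None


# ---------------------------------------------------------------------------
# run config


@dataclass
class RunConfig:
    """Validated run description with all defaults filled in."""

    scenario: Scenario
    times: tuple
    h: float = 0.5
    extent: Optional[float] = None
    out_dir: str = "out"
    write_grids: bool = True
    write_profiles: bool = True
    write_metrics: bool = True
    write_trajectories: bool = True
    write_png: bool = False
    log_level: str = "info"
    preset_name: Optional[str] = None


def config_from_dict(d: dict) -> RunConfig:
    if not isinstance(d, dict):
        raise ValidationError("config: expected a mapping")
    preset_name = d.get("preset")
    if preset_name is not None:
        from .presets import preset as get_preset

        p = get_preset(preset_name)
        sc = p.scenario
        default_times = p.snapshot_times
    elif "scenario" in d:
        sc = scenario_from_dict(d["scenario"])
        default_times = ()
    else:
        raise ValidationError("config: need either 'preset' or 'scenario'")
    times = tuple(float(t) for t in d.get("times", default_times))
    if not times:
        raise ValidationError("times: must be a non-empty list")
    if any(t < 0 for t in times):
        raise ValidationError("times: snapshot times must be >= 0")
    grid = d.get("grid", {})
    h = float(grid.get("h", 0.5))
    if h <= 0:
        raise ValidationError(f"grid.h: must be > 0, got {h}")
    extent = float(grid["extent"]) if "extent" in grid and grid["extent"] else None
    outputs = d.get("outputs", {})
    return RunConfig(
        scenario=sc,
        times=times,
        h=h,
        extent=extent,
        out_dir=str(d.get("out", "out")),
        write_grids=bool(outputs.get("grids", True)),
        write_profiles=bool(outputs.get("profiles", True)),
        write_metrics=bool(outputs.get("metrics", True)),
        write_trajectories=bool(outputs.get("trajectories", True)),
        write_png=bool(outputs.get("png", False)),
        log_level=str(d.get("log_level", "info")),
        preset_name=preset_name,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run config."""
    if not os.path.exists(path):
        raise IOError(f"config file not found: {path}")
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return config_from_dict(data)


def normalize(d: dict) -> dict:
    """Canonical form of a scenario mapping: the dump of its load."""
    return scenario_to_dict(scenario_from_dict(d))


def dump_scenario_yaml(sc: Scenario) -> str:
    return yaml.safe_dump(scenario_to_dict(sc), sort_keys=True)


# ---------------------------------------------------------------------------
# run


def _fmt_time(t: float) -> str:
    return format(float(t), "g").replace(".", "p").replace("-", "m")


def _write_profile_csv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("angle,class,class_name,start,end\n")
        for cls, start, end in profile.segments:
            fh.write(
                f"{_fmt(profile.angle)},{cls},{CLASS_NAMES[cls]},"
                f"{_fmt(start)},{_fmt(end)}\n"
            )


def _write_metrics_csv(rows, path) -> None:
    cols = [
        "t",
        "ray",
        "focus_width",
        "inner_gap_width",
        "core_width",
        "light_width",
        "outer_width",
        "radius",
        "light_proportion",
        "inside_wide",
    ]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(row[c]) for c in cols) + "\n")


def _write_trajectories_tsv(sc: Scenario, path) -> None:
    from .kinematics import stopping_time

    with open(path, "w") as fh:
        fh.write("organiser\ttrain\twindow\tlabel\tt\tx\tv\tstopped\n")
        for oi, org in enumerate(sc.organisers):
            for ti, tr in enumerate(org.trains):
                for wi, w in enumerate(tr.windows):
                    if isinstance(sc.field, UniformField):
                        t_end = w.start + stopping_time(w.v0, sc.field.a) + 1.0
                    else:
                        t_end = w.start + 100.0
                    grid = np.linspace(w.start, t_end, 51)
                    traj = trajectory(
                        MotionParams(w.v0, w.start), sc.field.along_ray(0.0), grid
                    )
                    for t, x, v, s in zip(traj.t, traj.x, traj.v, traj.stopped):
                        fh.write(
                            f"{oi}\t{ti}\t{wi}\t{w.label}\t"
                            f"{_fmt(t)}\t{_fmt(x)}\t{_fmt(v)}\t{s}\n"
                        )


def run(config: RunConfig) -> list:
    """Execute a run config; returns the list of files written.

    Per snapshot time: a PGM grid (optionally PNG), a radial-profile CSV;
    plus one metrics CSV with a row per snapshot and one trajectories TSV.
    Identical inputs give byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    os.makedirs(config.out_dir, exist_ok=True)
    written = []
    metric_rows = []
    for t in config.times:
        tag = _fmt_time(t)
        if config.write_grids:
            grid = render_grid(config.scenario, t, config.h, config.extent)
            p = os.path.join(config.out_dir, f"grid_t{tag}.pgm")
            grid.to_pgm(p)
            written.append(p)
            if config.write_png:
                p = os.path.join(config.out_dir, f"grid_t{tag}.png")
                grid.to_png(p)
                written.append(p)
        prof = radial_profile(config.scenario, t, 0.0)
        if config.write_profiles:
            p = os.path.join(config.out_dir, f"profile_t{tag}.csv")
            _write_profile_csv(prof, p)
            written.append(p)
        if config.write_metrics:
            m = measure_rings(prof)
            metric_rows.append(
                {
                    "t": t,
                    "ray": 0.0,
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
        log.info("snapshot t=%s done", t)
    if config.write_metrics:
        p = os.path.join(config.out_dir, "metrics.csv")
        _write_metrics_csv(metric_rows, p)
        written.append(p)
    if config.write_trajectories:
        p = os.path.join(config.out_dir, "trajectories.tsv")
        _write_trajectories_tsv(config.scenario, p)
        written.append(p)
    return written
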