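"""Scene configuration files, trajectory/metric tables, geometry export.

Scenes are human-readable YAML with a ``schema_version`` key.  All lengths
are SI meters; any length key may alternatively carry a ``_cm`` or ``_mm``
suffix (e.g. ``radius_mm: 0.625``) and is converted on load.  Unknown keys
are rejected with the offending key named.  Trajectories and metrics are
plain CSV with units in the header names; centerlines export as Wavefront
OBJ polylines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quaternion as quat
from .collision import CylinderCollider, PlaneCollider, SphereCollider
from .errors import SchemaError
from .experiments import ExperimentResult, elongation_metric
from .solver import World, step
from .state import SimConfig, build_rod, conform_to_centerline, make_spiral_centerline

__all__ = [
    "SceneConfig",
    "load_scene",
    "save_scene",
    "build_world",
    "run_scene",
    "write_trajectory",
    "read_trajectory",
    "export_centerline_obj",
]

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "seed", "duration", "sim", "rods", "colliders", "boundaries", "output"}
_SIM_KEYS = {"dt", "iterations", "use_ddc", "gravity", "friction_k", "cell_size", "collision_enabled"}
_ROD_KEYS = {
    "name", "shape", "n_elements", "total_length", "radius",
    "stiffness_bend", "stiffness_twist", "stiffness_stretch",
    "damping_linear", "damping_angular", "mass",
}
_SHAPE_KEYS = {
    "line": {"type", "start", "direction"},
    "spiral": {"type", "helix_radius", "pitch", "axis", "origin"},
    "points": {"type", "points"},
}
_COLLIDER_KEYS = {
    "plane": {"type", "normal", "offset", "friction_k"},
    "sphere": {"type", "center", "radius", "friction_k"},
    "cylinder": {"type", "point", "axis", "radius", "friction_k"},
}
_BOUNDARY_KEYS = {
    "pin": {"type", "rod", "particle"},
    "pin_orientation": {"type", "rod", "element"},
    "move_linear": {"type", "rod", "particle", "to", "t0", "t1"},
    "rotate_element": {"type", "rod", "element", "axis", "angle", "t0", "t1"},
}
_OUTPUT_KEYS = {"trajectory", "every"}

_UNIT_SCALE = {"_m": 1.0, "_cm": 1e-2, "_mm": 1e-3}


def _canonicalize_units(d: dict, context: str) -> dict:
    """Strip ``_m``/``_cm``/``_mm`` suffixes, converting values to meters."""
    out: dict = {}
    for key, value in d.items():
        base, scale = key, None
        for suffix, s in _UNIT_SCALE.items():
            if key.endswith(suffix) and len(key) > len(suffix):
                base, scale = key[: -len(suffix)], s
                break
        if scale is not None:
            if isinstance(value, (list, tuple)):
                value = [v * scale for v in value]
            elif isinstance(value, (int, float)):
                value = value * scale
            else:
                raise SchemaError(f"unit-suffixed key '{key}' in {context} must be numeric")
        if base in out:
            raise SchemaError(f"duplicate key '{base}' in {context}")
        out[base] = value
    return out


def _check_keys(d: dict, allowed: set, context: str) -> None:
    for key in d:
        if key not in allowed:
            raise SchemaError(f"unknown key '{key}' in {context}")


def _check_typed(entry: dict, table: dict, context: str) -> dict:
    if "type" not in entry:
        raise SchemaError(f"missing 'type' in {context}")
    t = entry["type"]
    if t not in table:
        raise SchemaError(f"unknown type '{t}' in {context}")
    _check_keys(entry, table[t], f"{context} (type {t})")
    return entry


@dataclass
class SceneConfig:
    """Validated scene description; round-trips losslessly through YAML."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    duration: float = 1.0
    sim: dict = field(default_factory=dict)
    rods: list = field(default_factory=list)
    colliders: list = field(default_factory=list)
    boundaries: list = field(default_factory=list)
    output: dict = field(default_factory=lambda: {"trajectory": True, "every": 1})


def _validate(raw: dict, context: str = "scene") -> SceneConfig:
    if not isinstance(raw, dict):
        raise SchemaError("scene file must contain a mapping")
    raw = _canonicalize_units(raw, context)
    _check_keys(raw, _TOP_KEYS, context)
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {raw.get('schema_version')!r}")
    sim = _canonicalize_units(raw.get("sim", {}) or {}, "sim")
    _check_keys(sim, _SIM_KEYS, "sim")
    rods = []
    for i, rod in enumerate(raw.get("rods", []) or []):
        ctx = f"rods[{i}]"
        rod = _canonicalize_units(rod, ctx)
        _check_keys(rod, _ROD_KEYS, ctx)
        for req in ("n_elements", "total_length", "radius"):
            if req not in rod:
                raise SchemaError(f"missing key '{req}' in {ctx}")
        if rod["radius"] <= 0:
            raise SchemaError(f"'radius' must be positive in {ctx}")
        if rod["total_length"] <= 0:
            raise SchemaError(f"'total_length' must be positive in {ctx}")
        shape = _canonicalize_units(rod.get("shape", {"type": "line"}), f"{ctx}.shape")
        rod["shape"] = _check_typed(shape, _SHAPE_KEYS, f"{ctx}.shape")
        rods.append(rod)
    colliders = []
    for i, col in enumerate(raw.get("colliders", []) or []):
        ctx = f"colliders[{i}]"
        col = _canonicalize_units(col, ctx)
        colliders.append(_check_typed(col, _COLLIDER_KEYS, ctx))
    boundaries = []
    for i, b in enumerate(raw.get("boundaries", []) or []):
        ctx = f"boundaries[{i}]"
        b = _canonicalize_units(b, ctx)
        boundaries.append(_check_typed(b, _BOUNDARY_KEYS, ctx))
    output = raw.get("output", {"trajectory": True, "every": 1}) or {}
    _check_keys(output, _OUTPUT_KEYS, "output")
    output = {"trajectory": output.get("trajectory", True), "every": output.get("every", 1)}
    return SceneConfig(
        schema_version=SCHEMA_VERSION,
        seed=int(raw.get("seed", 0)),
        duration=float(raw.get("duration", 1.0)),
        sim=sim,
        rods=rods,
        colliders=colliders,
        boundaries=boundaries,
        output=output,
    )


def load_scene(path) -> SceneConfig:
    """Load and validate a YAML scene file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scene file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate(raw)


def save_scene(scene: SceneConfig, path) -> Path:
    """Write a scene in canonical form (SI units, sorted keys)."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(scene), fh, sort_keys=True)
    return path


def _make_collider(spec: dict):
    t = spec["type"]
    if t == "plane":
        return PlaneCollider(spec["normal"], spec["offset"], spec.get("friction_k"))
    if t == "sphere":
        return SphereCollider(spec["center"], spec["radius"], spec.get("friction_k"))
    return CylinderCollider(spec["point"], spec["axis"], spec["radius"], spec.get("friction_k"))


def _rod_points(spec: dict) -> np.ndarray:
    shape = spec["shape"]
    n = int(spec["n_elements"])
    L = float(spec["total_length"])
    t = shape["type"]
    if t == "line":
        start = np.asarray(shape.get("start", (0.0, 0.0, 0.0)), dtype=float)
        direction = np.asarray(shape.get("direction", (0.0, 0.0, 1.0)), dtype=float)
        direction = direction / np.linalg.norm(direction)
        return start + np.linspace(0.0, L, n + 1)[:, None] * direction
    if t == "spiral":
        return make_spiral_centerline(
            L, n, shape.get("helix_radius", 0.004), shape.get("pitch", 0.008),
            axis=shape.get("axis", (0.0, 0.0, 1.0)),
            origin=shape.get("origin", (0.0, 0.0, 0.0)),
        )
    return np.asarray(shape["points"], dtype=float)


def build_world(scene: SceneConfig) -> World:
    """Instantiate a :class:`World` (rods, colliders, boundary scripts) from a
    validated scene."""
    sim_kwargs = dict(scene.sim)
    cfg = SimConfig(seed=scene.seed, **sim_kwargs)
    rod_states = []
    for spec in scene.rods:
        pts = _rod_points(spec)
        rod, ps, os_ = build_rod(
            pts,
            radius=float(spec["radius"]),
            stiffness_bend=spec.get("stiffness_bend", 0.05),
            stiffness_twist=spec.get("stiffness_twist", 0.25),
            stiffness_stretch=spec.get("stiffness_stretch", 1.0),
            damping_linear=spec.get("damping_linear", 0.1),
            damping_angular=spec.get("damping_angular", 0.1),
            mass=spec.get("mass", 1.0),
            name=spec.get("name", "rod"),
        )
        rod_states.append((rod, ps, os_))
    colliders = [_make_collider(c) for c in scene.colliders]
    world = World.from_rods(rod_states, cfg, colliders=colliders)
    scripts = []
    for b in scene.boundaries:
        rod = world.rods[int(b.get("rod", 0))]
        if b["type"] == "pin":
            world.winv[rod.particle_start + int(b["particle"])] = 0.0
        elif b["type"] == "pin_orientation":
            world.winv_q[rod.element_start + int(b["element"])] = 0.0
        elif b["type"] == "move_linear":
            idx = rod.particle_start + int(b["particle"])
            world.winv[idx] = 0.0
            start = world.x[idx].copy()
            target = np.asarray(b["to"], dtype=float)
            t0, t1 = float(b["t0"]), float(b["t1"])

            def move(world_, t, idx=idx, start=start, target=target, t0=t0, t1=t1):
                frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
                world_.x[idx] = (1.0 - frac) * start + frac * target

            scripts.append(move)
        elif b["type"] == "rotate_element":
            eidx = rod.element_start + int(b["element"])
            world.winv_q[eidx] = 0.0
            q0 = world.q[eidx].copy()
            axis = np.asarray(b["axis"], dtype=float)
            angle = float(b["angle"])
            t0, t1 = float(b["t0"]), float(b["t1"])

            def rot(world_, t, eidx=eidx, q0=q0, axis=axis, angle=angle, t0=t0, t1=t1):
                frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
                world_.q[eidx] = quat.multiply(
                    quat.from_axis_angle(axis, angle * frac), q0
                )

            scripts.append(rot)
    world.scripts.extend(scripts)
    return world


def run_scene(scene: SceneConfig, progress=None) -> ExperimentResult:
    """Simulate a scene for its configured duration, recording the rod-0
    elongation metric and (optionally) the full trajectory."""
    world = build_world(scene)
    cfg = world.config
    n_steps = int(round(scene.duration / cfg.dt))
    every = max(int(scene.output.get("every", 1)), 1)
    record = bool(scene.output.get("trajectory", True))
    rod = world.rods[0]
    frames_idx, elong, traj = [], [], []
    for s in range(n_steps):
        report = step(world, compute_report=False)
        if (s + 1) % every == 0 or s == n_steps - 1:
            frames_idx.append(s)
            psl, _ = world.rod_slices(rod)
            elong.append(elongation_metric(rod, world.x[psl]))
            if record:
                traj.append(world.x.copy())
        if progress is not None:
            progress(s, n_steps, report)
    frames = pd.DataFrame({"frame": frames_idx, "elongation_pct": elong})
    return ExperimentResult(
        frames=frames,
        summary={
            "final_elongation_pct": float(elong[-1]) if elong else 0.0,
            "max_elongation_pct": float(max(elong)) if elong else 0.0,
        },
        config={"scene": "custom", **{k: v for k, v in asdict(scene).items() if k != "rods"}},
        seed=scene.seed,
        trajectory=np.array(traj) if traj else None,
    )


def write_trajectory(result: ExperimentResult, path) -> tuple[Path, Path]:
    """Write a result as two CSV tables.

    ``<path>.trajectory.csv`` holds one row per recorded frame per particle
    (frame, particle, x_m, y_m, z_m); ``<path>.metrics.csv`` holds the
    per-frame metric series.  Both are deterministic given identical inputs.
    """
    base = Path(path)
    traj_path = base.with_suffix(base.suffix + ".trajectory.csv") if base.suffix else Path(str(base) + ".trajectory.csv")
    metrics_path = Path(str(base) + ".metrics.csv")
    if result.trajectory is None:
        raise ValueError("result holds no trajectory; enable trajectory recording")
    frames, n, _ = result.trajectory.shape
    frame_ids = (
        np.asarray(result.frames["frame"])[:frames]
        if len(result.frames) >= frames
        else np.arange(frames)
    )
    rows = pd.DataFrame(
        {
            "frame": np.repeat(frame_ids[:frames], n),
            "particle": np.tile(np.arange(n), frames),
            "x_m": result.trajectory[:, :, 0].ravel(),
            "y_m": result.trajectory[:, :, 1].ravel(),
            "z_m": result.trajectory[:, :, 2].ravel(),
        }
    )
    rows.to_csv(traj_path, index=False, float_format="%.17g")
    result.frames.to_csv(metrics_path, index=False, float_format="%.17g")
    return traj_path, metrics_path


def read_trajectory(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Parse back a trajectory/metrics pair written by :func:`write_trajectory`."""
    traj_path = Path(str(path) + ".trajectory.csv")
    metrics_path = Path(str(path) + ".metrics.csv")
    rows = pd.read_csv(traj_path)
    frames = rows["frame"].nunique()
    n = rows["particle"].nunique()
    traj = rows[["x_m", "y_m", "z_m"]].to_numpy().reshape(frames, n, 3)
    return traj, pd.read_csv(metrics_path)


def export_centerline_obj(positions: np.ndarray, path) -> Path:
    """Write the centerline as a Wavefront OBJ polyline (v records plus one
    l record with 1-based indices)."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for a polyline")
    path = Path(path)
    with open(path, "w") as fh:
        for p in pts:
            fh.write(f"v {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write("l " + " ".join(str(i + 1) for i in range(pts.shape[0])) + "\n")
    return path
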