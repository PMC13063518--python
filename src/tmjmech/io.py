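"""File formats: meshes (STL/PLY/OBJ), recordings and curves (CSV),
landmarks/models/tasks/results (JSON).

All files use the mm-N-MPa-s unit convention; configuration blocks carry
an explicit ``units`` field that is validated against it. PLY export
attaches per-vertex scalar fields as the standard ``quality`` property
(ASCII), so gap and congruency maps round-trip through common mesh
viewers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .constitutive import (ElasticFoundationParams, HillMuscleParams,
                           LigamentParams)
from .core import InvalidInputError, ScalarField, TriangleMesh, UniformSeries
from .morphometrics import LandmarkSelectionSet
from .signals import EMG_CHANNELS, BiteRecording, ProcessedTask
from .simulator import (JointSite, Ligament, Muscle, MusculoskeletalModel,
                        SimulationResult)

log = logging.getLogger("tmjmech")

UNITS = "mm-N-MPa-s"
MESH_EXTENSIONS = (".stl", ".ply", ".obj")


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration: paths, units declaration, seed."""

    units: str = UNITS
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        validate_units(self.units)


def validate_units(units: str) -> None:
    if units != UNITS:
        raise InvalidInputError(
            f"config field 'units' must read {UNITS!r}, got {units!r}")


def config_hash(obj) -> str:
    """Stable hash of a JSON-serializable configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# meshes

def read_mesh(path) -> tuple[TriangleMesh, ScalarField | None]:
    """Read STL/PLY/OBJ; PLY per-vertex ``quality`` is restored as a field."""
    path = Path(path)
    if path.suffix.lower() not in MESH_EXTENSIONS:
        raise InvalidInputError(f"unsupported mesh extension {path.suffix!r}")
    if path.suffix.lower() == ".ply":
        parsed = _try_read_ply_quality(path)
        if parsed is not None:
            return parsed
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse mesh {path}: {exc}") from exc
    mesh = TriangleMesh(np.asarray(tm.vertices, float),
                        np.asarray(tm.faces, np.int64))
    return mesh, None


def _try_read_ply_quality(path: Path):
    """Parse an ASCII PLY whose vertices carry x y z quality; None otherwise."""
    try:
        with open(path, "r") as fh:
            if fh.readline().strip() != "ply":
                return None
            props, n_vert, n_face, in_vertex = [], None, None, False
            for line in fh:
                tok = line.split()
                if not tok:
                    continue
                if tok[0] == "format" and tok[1] != "ascii":
                    return None
                if tok[0] == "element":
                    in_vertex = tok[1] == "vertex"
                    if tok[1] == "vertex":
                        n_vert = int(tok[2])
                    elif tok[1] == "face":
                        n_face = int(tok[2])
                if tok[0] == "property" and in_vertex and tok[1] != "list":
                    props.append(tok[2])
                if tok[0] == "end_header":
                    break
            if n_vert is None or n_face is None or "quality" not in props:
                return None
            data = np.loadtxt(fh, max_rows=n_vert).reshape(n_vert, len(props))
            faces = np.loadtxt(fh, max_rows=n_face, dtype=np.int64
                               ).reshape(n_face, -1)[:, 1:4]
        cols = {p: i for i, p in enumerate(props)}
        verts = data[:, [cols["x"], cols["y"], cols["z"]]]
        mesh = TriangleMesh(verts, faces)
        field = ScalarField(mesh, data[:, cols["quality"]], name="quality")
        return mesh, field
    except (OSError, ValueError):
        return None


def write_mesh(mesh: TriangleMesh, path, scalar_field: ScalarField | None = None) -> None:
    """Write a mesh; with a scalar field the format must be PLY (ASCII)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in MESH_EXTENSIONS:
        raise InvalidInputError(f"unsupported mesh extension {ext!r}")
    if scalar_field is not None:
        if ext != ".ply":
            raise InvalidInputError("per-vertex scalar export requires .ply")
        _write_ply_quality(mesh, scalar_field.values, path)
        return
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def _write_ply_quality(mesh: TriangleMesh, values: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, q in zip(mesh.vertices, values):
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {q:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_field_csv(field: ScalarField, path) -> None:
    pd.DataFrame({"vertex": np.arange(field.mesh.n_vertices),
                  f"{field.name}_{field.units}".rstrip("_"): field.values}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# recordings and curves

def read_recording_csv(path, task_side: str = "left") -> BiteRecording:
    """Read a ``t,force,LT,RT,LM,RM`` CSV (t in s, force in N, 2000 Hz-class).

    Sample uniformity of the time column is validated to 1e-6 s; extra
    columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    required = ["t", "force", *EMG_CHANNELS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"recording CSV missing columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"ignoring extra recording columns {extra}")
        log.warning("ignoring extra recording columns %s", extra)
    t = df["t"].to_numpy(float)
    dt = np.diff(t)
    if len(dt) < 1 or np.ptp(dt) > 1e-6:
        raise InvalidInputError("time column is not uniform within 1e-6 s")
    rate = 1.0 / float(np.mean(dt))
    force = UniformSeries(rate, df["force"].to_numpy(float), start_time=float(t[0]))
    emg = {ch: UniformSeries(rate, df[ch].to_numpy(float), start_time=float(t[0]))
           for ch in EMG_CHANNELS}
    return BiteRecording(force=force, emg=emg, task_side=task_side)


def write_recording_csv(rec: BiteRecording, path) -> None:
    data = {"t": rec.force.times, "force": rec.force.values}
    for ch in EMG_CHANNELS:
        data[ch] = rec.emg[ch].values
    pd.DataFrame(data).to_csv(path, index=False)


def write_curve_csv(series: UniformSeries, path, column: str = "force") -> None:
    pd.DataFrame({"t": series.times, column: series.values}).to_csv(path, index=False)


def read_curve_csv(path, column: str = "force") -> UniformSeries:
    df = pd.read_csv(path)
    if "t" not in df.columns or column not in df.columns:
        raise InvalidInputError(f"curve CSV needs columns 't' and {column!r}")
    t = df["t"].to_numpy(float)
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise InvalidInputError("time column is not uniform within 1e-6 s")
    return UniformSeries(1.0 / float(np.mean(dt)), df[column].to_numpy(float),
                         start_time=float(t[0]))


def write_processed_task(task: ProcessedTask, json_path, curve_path=None) -> None:
    payload = {"units": UNITS,
               "ic_temporalis": task.ic_temporalis,
               "ic_masseter": task.ic_masseter,
               "final_bite_force_N": task.final_bite_force}
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if curve_path is not None:
        write_curve_csv(task.force_curve, curve_path)


# ---------------------------------------------------------------------------
# landmarks

def read_landmarks_json(path) -> dict[str, LandmarkSelectionSet]:
    """``{name: [[x,y,z], ...]}`` in mm, one entry per observer repetition."""
    data = json.loads(Path(path).read_text())
    return {name: LandmarkSelectionSet(name=name, selections=np.asarray(pts, float))
            for name, pts in data.items()}


# ---------------------------------------------------------------------------
# model / task / result JSON

def model_to_dict(model: MusculoskeletalModel) -> dict:
    return {
        "units": UNITS,
        "mass_kg": model.mass,
        "inertia_diag_kgm2": model.inertia_diag.tolist(),
        "com": model.com.tolist(),
        "task_side": model.task_side,
        "gravity": model.gravity,
        "damping": list(model.damping),
        "menton": model.menton.tolist(),
        "condyle_tops": {k: v.tolist() for k, v in model.condyle_tops.items()},
        "bite_points": {k: v.tolist() for k, v in model.bite_points.items()},
        "muscles": [{
            "name": m.name, "side": m.side, "group": m.group,
            "origin": m.origin.tolist(), "insertion": m.insertion.tolist(),
            "max_isometric_force_N": m.params.max_isometric_force,
            "optimal_length_mm": m.params.optimal_length,
            "active": m.active,
        } for m in model.muscles],
        "ligaments": [{
            "name": l.name, "side": l.side,
            "origin": l.origin.tolist(), "insertion": l.insertion.tolist(),
            "stiffness_N_per_strain": l.params.stiffness,
            "initial_length_mm": l.params.initial_length,
            "slack_length_mm": l.params.slack_length,
        } for l in model.ligaments],
        "joint_sites": [{
            "side": s.side, "sphere_center": s.sphere_center.tolist(),
            "sphere_radius_mm": s.sphere_radius,
            "socket_center": s.socket_center.tolist(),
            "socket_radius_mm": s.socket_radius,
            "elastic_foundation": {"thickness_mm": s.ef.thickness,
                                   "elastic_modulus_MPa": s.ef.elastic_modulus,
                                   "poisson": s.ef.poisson},
        } for s in model.joint_sites],
    }


def model_from_dict(d: dict) -> MusculoskeletalModel:
    validate_units(d.get("units", ""))
    muscles = tuple(Muscle(
        name=m["name"], side=m["side"], group=m["group"],
        origin=np.array(m["origin"]), insertion=np.array(m["insertion"]),
        params=HillMuscleParams(max_isometric_force=m["max_isometric_force_N"],
                                optimal_length=m["optimal_length_mm"]),
        active=m.get("active", True)) for m in d["muscles"])
    ligaments = tuple(Ligament(
        name=l["name"], side=l["side"],
        origin=np.array(l["origin"]), insertion=np.array(l["insertion"]),
        params=LigamentParams(stiffness=l["stiffness_N_per_strain"],
                              initial_length=l["initial_length_mm"],
                              slack_length=l["slack_length_mm"]))
        for l in d["ligaments"])
    sites = tuple(JointSite(
        side=s["side"], sphere_center=np.array(s["sphere_center"]),
        sphere_radius=s["sphere_radius_mm"],
        socket_center=np.array(s["socket_center"]),
        socket_radius=s["socket_radius_mm"],
        ef=ElasticFoundationParams(
            thickness=s["elastic_foundation"]["thickness_mm"],
            elastic_modulus=s["elastic_foundation"]["elastic_modulus_MPa"],
            poisson=s["elastic_foundation"]["poisson"]))
        for s in d["joint_sites"])
    return MusculoskeletalModel(
        mass=d["mass_kg"], inertia_diag=np.array(d["inertia_diag_kgm2"]),
        com=np.array(d["com"]), muscles=muscles, ligaments=ligaments,
        joint_sites=sites,
        bite_points={k: np.array(v) for k, v in d["bite_points"].items()},
        condyle_tops={k: np.array(v) for k, v in d["condyle_tops"].items()},
        menton=np.array(d["menton"]), task_side=d.get("task_side", "left"),
        gravity=d.get("gravity", True),
        damping=tuple(d.get("damping", (150.0, 0.3))))


def write_model_json(model: MusculoskeletalModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def read_model_json(path) -> MusculoskeletalModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def read_task_json(path) -> dict:
    """Task spec: side, IC ratios, force-curve CSV path, weights, dt."""
    d = json.loads(Path(path).read_text())
    validate_units(d.get("units", ""))
    if "ratios" not in d or not set(d["ratios"]) <= {"temporalis", "masseter"}:
        raise InvalidInputError("task 'ratios' must give temporalis/masseter")
    return d


def write_result_json(result: SimulationResult, path,
                      histories_csv=None) -> None:
    from .simulator import summarize_joint_loading

    summary = summarize_joint_loading(result)
    payload = {
        "units": UNITS,
        "task_side": result.task_side,
        "terminal_bite_force_N": result.terminal_bite_force,
        "terminal_joint_force_N": {
            s: float(np.linalg.norm(result.terminal_joint_force(s)))
            for s in ("left", "right")},
        "joint_force_percent_of_bite": summary,
        "saturated": result.saturated,
        "equilibrium_residual": {"force_N": result.equilibrium_residual[0],
                                 "torque_Nmm": result.equilibrium_residual[1]},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    if histories_csv is not None:
        df = pd.DataFrame({"t": result.times,
                           "target_N": result.target_force,
                           "bite_N": result.bite_force})
        for i, name in enumerate(result.muscle_names):
            df[f"a_{name}"] = result.activations[:, i]
        for side, hist in (("left", result.joint_force_left),
                           ("right", result.joint_force_right)):
            df[f"joint_{side}_N"] = np.linalg.norm(hist, axis=1)
        df.to_csv(histories_csv, index=False)
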