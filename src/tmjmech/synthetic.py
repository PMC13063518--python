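"""Synthetic fixtures with known ground truth.

Three families of generators make the whole pipeline testable without
any recorded data:

* ``gen_bite_recording`` — a five-bite unilateral clench (10-50 N target
  staircase at 2000 Hz) with band-limited EMG carriers whose envelopes
  encode prescribed ipsilateral/contralateral activation ratios;
* ``gen_surface`` / ``gen_condyle_fossa_pair`` — analytic articular
  surface patches meshed near the 0.3 mm working edge length, with
  closed-form curvature and clearance fields attached;
* ``gen_toy_mandible`` — a bilaterally symmetric musculoskeletal model
  (six muscles and seven ligaments per side, elastic-foundation condylar
  sites, premolar/incisor bite landmarks) sized to a condyle-top-to-
  menton length of 117.8 mm by default.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .constitutive import (ElasticFoundationParams, HillMuscleParams,
                           LigamentParams)
from .core import InvalidInputError, TriangleMesh, UniformSeries
from .signals import BiteRecording
from .simulator import JointSite, Ligament, Muscle, MusculoskeletalModel

# ---------------------------------------------------------------------------
# bite recordings


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def gen_bite_recording(plateau: float = 50.0, ic_temporalis: float = 1.0,
                       ic_masseter: float = 1.0, task_side: str = "left",
                       fs: float = 2000.0, noise_sd: float = 0.05,
                       seed: int = 0) -> tuple[BiteRecording, dict]:
    """Five-bite unilateral task with prescribed IC ratios and plateau force.

    The force channel ramps through five smooth ramp-hold bites at the
    10-50 N guided levels scaled so the highest bite plateaus at
    ``plateau`` N. Each EMG pair shares one band-limited (20-450 Hz)
    Gaussian carrier, amplitude-modulated in proportion to force; the
    ipsilateral modulation additionally ramps from unity at the 20 N
    calibration bite to the prescribed IC ratio at the task bite, so the
    baseline-normalized envelope ratio over the task window equals the
    prescribed value. ``noise_sd`` adds independent relative amplitude
    noise per channel. Returns the recording plus a ground-truth dict
    with the prescribed values and the analysis windows.
    """
    if plateau <= 0 or ic_temporalis <= 0 or ic_masseter <= 0:
        raise InvalidInputError("plateau and ratios must be positive")
    rng = np.random.default_rng(seed)
    rest, ramp, hold = 0.4, 0.25, 1.0
    levels = np.array([10.0, 20.0, 30.0, 40.0, 50.0]) * plateau / 50.0
    period = rest + ramp + hold
    total = 5 * period + rest
    n = int(round(total * fs))
    t = np.arange(n) / fs

    force = np.zeros(n)
    windows = []
    for k, lvl in enumerate(levels):
        t0 = rest + k * period
        up = _smoothstep((t - t0) / ramp)
        down = _smoothstep((t - (t0 + ramp + hold)) / ramp)
        force += lvl * (up - down)
        windows.append((t0 + ramp + 0.1, t0 + ramp + hold - 0.1))
    baseline_window = windows[1]  # 20 N bite plateau
    bite_window = windows[4]      # task (highest) bite plateau
    last_release = rest + 4 * period + ramp + hold + ramp
    rest_windows = [(0.05, rest - 0.05), (last_release + 0.02, total - 0.02)]
    force_noisy = force + noise_sd * rng.standard_normal(n)

    # ipsilateral extra drive: 1 at the 20 N level, prescribed ratio at plateau
    f20 = levels[1]
    frac = np.clip((force - f20) / max(plateau - f20, 1e-9), 0.0, None)

    def carrier() -> np.ndarray:
        b, a = butter(4, [20.0 / (fs / 2), 450.0 / (fs / 2)], btype="band")
        return filtfilt(b, a, rng.standard_normal(n))

    emg = {}
    base_mod = 0.05 + force / plateau
    for group, ratio, ch_ipsi, ch_contra in (
            ("temporalis", ic_temporalis, "LT", "RT"),
            ("masseter", ic_masseter, "LM", "RM")):
        if task_side == "right":
            ch_ipsi, ch_contra = ch_contra, ch_ipsi
        carr = carrier()
        m_ipsi = base_mod * (1.0 + (ratio - 1.0) * frac)
        for ch, mod in ((ch_ipsi, m_ipsi), (ch_contra, base_mod)):
            amp = mod * np.clip(1.0 + noise_sd * rng.standard_normal(n), 0.0, None)
            emg[ch] = UniformSeries(fs, amp * carr)

    rec = BiteRecording(force=UniformSeries(fs, force_noisy), emg=emg,
                        task_side=task_side)
    truth = {"plateau": plateau, "ic_temporalis": ic_temporalis,
             "ic_masseter": ic_masseter, "bite_window": bite_window,
             "baseline_window": baseline_window, "rest_windows": rest_windows,
             "clean_force": force}
    return rec, truth


# ---------------------------------------------------------------------------
# analytic surfaces


def _grid_mesh(nx: int, ny: int) -> np.ndarray:
    """Faces of an (nx+1) x (ny+1) point grid, alternating diagonals."""
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = a + 1
            c = a + (ny + 1)
            d = c + 1
            if (i + j) % 2 == 0:
                faces.append((a, b, d)); faces.append((a, d, c))
            else:
                faces.append((a, b, c)); faces.append((b, d, c))
    return np.array(faces, dtype=np.int64)


def _monge_curvatures(fx, fy, fxx, fxy, fyy):
    """Principal curvatures of z = f(x, y), positive = convex toward +z normal."""
    w2 = 1.0 + fx * fx + fy * fy
    w = np.sqrt(w2)
    e_mat = np.stack([1.0 + fx * fx, fx * fy, fx * fy, 1.0 + fy * fy],
                     axis=-1).reshape(-1, 2, 2)
    l_mat = np.stack([fxx, fxy, fxy, fyy], axis=-1).reshape(-1, 2, 2) / w[..., None, None]
    shape_op = np.linalg.solve(e_mat, l_mat)
    evals = np.linalg.eigvals(shape_op)
    k = -np.sort(np.real(evals), axis=1)  # convex-up positive
    return k[:, 0], k[:, 1]


def gen_surface(kind: str, params: dict | None = None,
                edge_length: float = 0.3) -> tuple[TriangleMesh, dict]:
    """Analytic patch mesh with ground-truth curvature.

    Kinds: ``plane`` (extent), ``sphere`` (radius, cap_angle), ``cylinder``
    (radius, length, arc), ``ellipsoid`` (a, b, c, extent), ``saddle``
    (a, b, extent). Returns (mesh, truth) where truth carries per-vertex
    analytic ``k_max``/``k_min`` (convex w.r.t. the attached outward
    normals positive).
    """
    p = dict(params or {})
    h = edge_length / ((2.0 + np.sqrt(2.0)) / 3.0)  # grid pitch -> mean edge

    if kind == "plane":
        ext = p.get("extent", 6.0)
        nx = max(int(round(ext / h)), 2)
        xs = np.linspace(-ext / 2, ext / 2, nx + 1)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        mesh = TriangleMesh(verts, _grid_mesh(nx, nx),
                            vertex_normals=np.tile([0.0, 0.0, 1.0], (len(verts), 1)))
        z = np.zeros(len(verts))
        return mesh, {"k_max": z, "k_min": z.copy()}

    if kind == "sphere":
        r = p.get("radius", 10.0)
        cap = p.get("cap_angle", 0.55)
        # azimuthal-equidistant parameterization of the cap (near-isometric)
        ext = 2.0 * r * cap
        nx = max(int(round(ext / h)), 4)
        us = np.linspace(-ext / 2, ext / 2, nx + 1)
        gu, gv = np.meshgrid(us, us, indexing="ij")
        rho = np.sqrt(gu ** 2 + gv ** 2) / r  # polar angle
        psi = np.arctan2(gv, gu)
        keep = rho.ravel() <= cap + 1e-12
        sin_r, cos_r = np.sin(rho.ravel()), np.cos(rho.ravel())
        verts = r * np.column_stack([sin_r * np.cos(psi.ravel()),
                                     sin_r * np.sin(psi.ravel()), cos_r])
        faces = _grid_mesh(nx, nx)
        mesh = _mask_mesh(verts, faces, keep)
        normals = mesh.vertices / r
        mesh.vertex_normals = normals
        k = np.full(mesh.n_vertices, 1.0 / r)
        return mesh, {"k_max": k, "k_min": k.copy()}

    if kind == "cylinder":
        r = p.get("radius", 5.0)
        length = p.get("length", 6.0)
        arc = p.get("arc", 1.2)  # radians of circumference
        n_arc = max(int(round(arc * r / h)), 4)
        n_len = max(int(round(length / h)), 4)
        th = np.linspace(-arc / 2, arc / 2, n_arc + 1)
        ys = np.linspace(-length / 2, length / 2, n_len + 1)
        gt, gy = np.meshgrid(th, ys, indexing="ij")
        verts = np.column_stack([r * np.sin(gt.ravel()), gy.ravel(),
                                 r * np.cos(gt.ravel())])
        normals = np.column_stack([np.sin(gt.ravel()),
                                   np.zeros(gt.size), np.cos(gt.ravel())])
        mesh = TriangleMesh(verts, _grid_mesh(n_arc, n_len), vertex_normals=normals)
        return mesh, {"k_max": np.full(mesh.n_vertices, 1.0 / r),
                      "k_min": np.zeros(mesh.n_vertices)}

    if kind in ("ellipsoid", "saddle"):
        if kind == "ellipsoid":
            a, b, c = p.get("a", 12.0), p.get("b", 9.0), p.get("c", 7.0)
            ext = p.get("extent", 5.0)

            def f(x, y):
                return c * np.sqrt(np.maximum(1.0 - x ** 2 / a ** 2 - y ** 2 / b ** 2, 1e-12))

            def derivs(x, y):
                # z = c s, s = sqrt(1 - x^2/a^2 - y^2/b^2)
                s = f(x, y) / c
                fx = -c * x / (a ** 2 * s)
                fy = -c * y / (b ** 2 * s)
                fxx = -c / (a ** 2 * s) - c * x ** 2 / (a ** 4 * s ** 3)
                fyy = -c / (b ** 2 * s) - c * y ** 2 / (b ** 4 * s ** 3)
                fxy = -c * x * y / (a ** 2 * b ** 2 * s ** 3)
                return fx, fy, fxx, fxy, fyy
        else:
            a, b = p.get("a", 10.0), p.get("b", 14.0)
            ext = p.get("extent", 6.0)

            def f(x, y):
                return 0.5 * (x ** 2 / a - y ** 2 / b)

            def derivs(x, y):
                return x / a, -y / b, np.full_like(x, 1.0 / a), \
                    np.zeros_like(x), np.full_like(x, -1.0 / b)

        nx = max(int(round(ext / h)), 4)
        xs = np.linspace(-ext / 2, ext / 2, nx + 1)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        x, y = gx.ravel(), gy.ravel()
        verts = np.column_stack([x, y, f(x, y)])
        fx, fy, fxx, fxy, fyy = derivs(x, y)
        normals = np.column_stack([-fx, -fy, np.ones_like(fx)])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        mesh = TriangleMesh(verts, _grid_mesh(nx, nx), vertex_normals=normals)
        kmax, kmin = _monge_curvatures(fx, fy, fxx, fxy, fyy)
        return mesh, {"k_max": kmax, "k_min": kmin}

    raise InvalidInputError(f"unknown surface kind {kind!r}")


def _mask_mesh(verts: np.ndarray, faces: np.ndarray, keep: np.ndarray) -> TriangleMesh:
    fmask = keep[faces].all(axis=1)
    used = np.zeros(len(verts), dtype=bool)
    used[np.unique(faces[fmask])] = True
    idx = -np.ones(len(verts), dtype=np.int64)
    idx[used] = np.arange(int(used.sum()))
    return TriangleMesh(verts[used], idx[faces[fmask]])


def gen_condyle_fossa_pair(condyle_r: float = 10.0, socket_r: float = 10.0,
                           clearance: float = 0.5, incongruence: float = 0.0,
                           edge_length: float = 0.3,
                           cap_angle: float = 0.5) -> tuple[TriangleMesh, TriangleMesh, np.ndarray]:
    """Convex condyle cap inside a concave fossa socket, with analytic gap.

    The fossa is the matching spherical socket of radius ``socket_r``
    offset so the apex gap equals ``clearance``; ``incongruence`` > 0
    stretches the socket laterally toward an ellipsoid (semi-axes
    ``socket_r*(1+incongruence), socket_r, socket_r``). Returns (condyle,
    fossa, analytic minimum-gap per condyle vertex in mm). Condyle
    normals point into the joint space (up), fossa normals down.
    """
    if socket_r < condyle_r:
        raise InvalidInputError("socket radius must be >= condyle radius")
    if clearance < 0:
        raise InvalidInputError("intersecting surfaces: clearance < 0")
    condyle, _ = gen_surface("sphere", {"radius": condyle_r, "cap_angle": cap_angle},
                             edge_length)
    z_s = condyle_r + clearance - socket_r
    fossa, _ = gen_surface("sphere", {"radius": socket_r,
                                      "cap_angle": cap_angle * 1.3}, edge_length)
    center = np.array([0.0, 0.0, z_s])
    scale = np.array([1.0 + incongruence, 1.0, 1.0])
    fverts = center + (fossa.vertices * scale)
    # outward (into joint space) normals of the stretched socket point inward/down
    nrm = (fossa.vertices / socket_r) / scale
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    fossa_out = TriangleMesh(fverts, fossa.faces, vertex_normals=-nrm)

    if incongruence == 0.0:
        gap = socket_r - np.linalg.norm(condyle.vertices - center, axis=1)
    else:
        gap = np.array([_dist_to_ellipsoid(v - center, socket_r * scale)
                        for v in condyle.vertices])
    return condyle, fossa_out, gap


def _dist_to_ellipsoid(p: np.ndarray, semi: np.ndarray) -> float:
    """Distance from an interior point to an axis-aligned ellipsoid surface."""
    from scipy.optimize import minimize_scalar

    def radial(tp):
        th, ph = tp
        q = semi * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                             np.cos(th)])
        return float(np.linalg.norm(q - p))

    # coarse grid + local refinement on the (theta, phi) chart
    ths = np.linspace(0.0, np.pi / 2, 40)
    phs = np.linspace(0.0, 2 * np.pi, 80, endpoint=False)
    best = min(((radial((th, ph)), th, ph) for th in ths for ph in phs))
    from scipy.optimize import minimize
    res = minimize(lambda v: radial(v), [best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    return float(res.fun)


# ---------------------------------------------------------------------------
# toy mandible

DEFAULT_MUSCLE_STRENGTHS = {
    "temporalis_anterior": 160.0, "temporalis_middle": 100.0,
    "temporalis_posterior": 100.0, "masseter_superficial": 190.0,
    "masseter_deep": 100.0, "medial_pterygoid": 300.0,
}

_LIGAMENT_SLACK = {
    "anterior": 4.0, "medial": 1.9, "lateral": 1.9, "posterior": 7.5,
    "lateral_temporomandibular": 4.0, "sphenomandibular": 0.0,
    "stylomandibular": 0.0,
}


def gen_toy_mandible(length: float = 117.8,
                     muscle_strengths: dict[str, float] | None = None,
                     task_side: str = "left", gravity: bool = True,
                     seed: int = 0) -> MusculoskeletalModel:
    """Bilaterally symmetric toy mandible sized to the given length (mm).

    Condyle tops sit at (+/-30, 0, 0); the occlusal plane is z = -40
    through the premolar tips and incisor; the menton's anterior
    coordinate is solved so the average condyle-top-to-menton distance
    equals ``length`` exactly. Each condyle is an elastic-foundation
    sphere-in-socket site pre-seated (just touching) along an
    anterior-superior direction with a small lateral bias, so clenching
    seats the condyles against the eminence-like wall and asymmetric
    tasks brace the balancing-side condyle laterally. ``seed`` is
    accepted for interface uniformity; the default build is
    deterministic geometry.
    """
    if not (90.0 < length < 150.0):
        raise InvalidInputError("mandible length outside (90, 150) mm")
    strengths = dict(DEFAULT_MUSCLE_STRENGTHS)
    if muscle_strengths:
        strengths.update(muscle_strengths)

    w = 30.0
    z_m = -12.0
    y_m2 = length ** 2 - w ** 2 - z_m ** 2
    if y_m2 <= 0:
        raise InvalidInputError("length incompatible with toy geometry")
    menton = np.array([0.0, np.sqrt(y_m2), z_m])

    condyle_tops = {"left": np.array([-w, 0.0, 0.0]),
                    "right": np.array([w, 0.0, 0.0])}
    sphere_r, clearance = 8.0, 0.5
    ef = ElasticFoundationParams()
    sites = []
    for side, sx in (("left", -1.0), ("right", 1.0)):
        center = np.array([sx * w, 0.0, -sphere_r])
        # pre-seat direction: each condyle just touches its socket against a
        # lateral + anterior-superior wall (lateral wedge; the balancing-side
        # condyle braces against it during asymmetric clenching)
        seat = np.array([sx * 0.68, 0.42, 0.601])
        seat /= np.linalg.norm(seat)
        sites.append(JointSite(side=side, sphere_center=center,
                               sphere_radius=sphere_r,
                               socket_center=center - clearance * seat,
                               socket_radius=sphere_r + clearance, ef=ef))

    # (stem, origin, insertion) per side; x given for the right side (+),
    # mirrored for the left. Origins on the cranium, insertions on the mandible.
    muscle_geo = {
        "temporalis_anterior": ((26.0, 36.0, 42.0), (25.0, 26.0, -2.0)),
        "temporalis_middle": ((27.0, 30.0, 46.0), (25.0, 24.0, -4.0)),
        "temporalis_posterior": ((28.0, 20.0, 38.0), (25.0, 22.0, -6.0)),
        "masseter_superficial": ((30.0, 52.0, -2.0), (27.0, 16.0, -46.0)),
        "masseter_deep": ((28.0, 46.0, -5.0), (26.0, 20.0, -40.0)),
        "medial_pterygoid": ((0.0, 22.0, -8.0), (24.0, 14.0, -44.0)),
    }
    muscles = []
    for stem, (orig, ins) in muscle_geo.items():
        group = "medial_pterygoid" if stem == "medial_pterygoid" else stem.split("_")[0]
        for side, sx in (("left", -1.0), ("right", 1.0)):
            origin = np.array([sx * orig[0], orig[1], orig[2]])
            insertion = np.array([sx * ins[0], ins[1], ins[2]])
            l0 = float(np.linalg.norm(origin - insertion))
            muscles.append(Muscle(
                name=f"{side}_{stem}", side=side, group=group,
                origin=origin, insertion=insertion,
                params=HillMuscleParams(max_isometric_force=strengths[stem],
                                        optimal_length=l0)))

    ligament_geo = {
        "anterior": ((30.0, 12.0, -4.0), (30.0, 6.0, -10.0)),
        "medial": ((24.0, 0.0, -4.0), (24.0, 0.0, -12.0)),
        "lateral": ((36.0, 0.0, -4.0), (36.0, 0.0, -12.0)),
        "posterior": ((30.0, -12.0, -2.0), (30.0, -6.0, -10.0)),
        "lateral_temporomandibular": ((36.0, 4.0, 0.0), (34.0, 8.0, -16.0)),
        "sphenomandibular": ((14.0, 10.0, 5.0), (22.0, 10.0, -30.0)),
        "stylomandibular": ((24.0, -20.0, -5.0), (28.0, 0.0, -42.0)),
    }
    ligaments = []
    for stem, (orig, ins) in ligament_geo.items():
        for side, sx in (("left", -1.0), ("right", 1.0)):
            origin = np.array([sx * orig[0], orig[1], orig[2]])
            insertion = np.array([sx * ins[0], ins[1], ins[2]])
            l0 = float(np.linalg.norm(origin - insertion))
            ligaments.append(Ligament(
                name=f"{side}_{stem}", side=side, origin=origin,
                insertion=insertion,
                params=LigamentParams(stiffness=250.0, initial_length=l0,
                                      slack_length=_LIGAMENT_SLACK[stem])))

    bite_points = {"left_premolar": np.array([-14.0, 60.0, -40.0]),
                   "right_premolar": np.array([14.0, 60.0, -40.0]),
                   "incisor": np.array([0.0, 76.0, -40.0])}

    return MusculoskeletalModel(
        mass=0.2, inertia_diag=np.array([3.2e-4, 2.5e-4, 4.0e-4]),
        com=np.array([0.0, 40.0, -28.0]),
        muscles=tuple(muscles), ligaments=tuple(ligaments),
        joint_sites=tuple(sites), bite_points=bite_points,
        condyle_tops=condyle_tops, menton=menton,
        task_side=task_side, gravity=gravity)


def ramp_hold_curve(plateau: float = 50.0, duration: float = 0.25,
                    n_out: int = 250, ramp_fraction: float = 0.6) -> UniformSeries:
    """Smooth ramp to ``plateau`` N followed by a hold (tracking target)."""
    t = np.linspace(0.0, duration, n_out)
    vals = plateau * _smoothstep(t / (ramp_fraction * duration))
    return UniformSeries(sample_rate=(n_out - 1) / duration, values=vals)
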