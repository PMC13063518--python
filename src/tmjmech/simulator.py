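"""Rigid-mandible forward dynamics with force tracking.

The mandible is a single rigid body moving against a fixed cranium. A
bilateral planar bite constraint holds three mandibular landmarks (left
and right first-premolar tips and the lower incisor) on the occlusal
plane, leaving two in-plane translations and one rotation about the
plane normal free. Muscles are Hill-type point-to-point elements (six
active per side: anterior/middle/posterior temporalis, superficial/deep
masseter, medial pterygoid), ligaments are tension-only cables, and each
condyle transmits load through an elastic-foundation sphere-in-socket
contact site approximating disc-mediated load transfer.

At every time step the muscle activations are found by a tracking
quadratic program

    min_a  1/2 w_c ||cbar - H_c a||^2 + 1/2 w_a a^T a
           + 1/2 w_d ||a_prev - a||^2     s.t. 0 <= a <= 1

where cbar is the target bite force normal to the bite plane and H_c is
the excitation-response matrix (bite-force output at the task-side
premolar per unit activation), assembled by unit-activation perturbation
with the current passive state subtracted. Ipsilateral/contralateral
activation ratios measured for the temporalis and masseter pairs are
imposed by linearly combining paired columns of H_c, reducing each pair
to a single bounded variable. The QP is strictly convex for w_a > 0 and
is solved exactly as a box-constrained least-squares problem (BVLS).

Because the three-landmark constraint determines the out-of-plane
statics, condylar loading develops through in-plane seating of the
condyles against their fossae (anterior-superior eminence loading plus
lateral bracing), which is how unilateral clenching loads the balancing
side. External units are mm-N-MPa-s; the integrator works in SI
internally. Coordinates: +x lateral-right, +y anterior, +z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import lsq_linear

from .constitutive import (ElasticFoundationParams, HillMuscleParams,
                           LigamentParams, PenetrationSaturationError,
                           ef_pressure, hill_static_force, ligament_force)
from .core import InvalidInputError, UniformSeries

MM = 1e-3  # mm -> m

MUSCLE_GROUPS = ("temporalis", "masseter", "medial_pterygoid")


# ---------------------------------------------------------------------------
# model data types

@dataclass(frozen=True)
class Muscle:
    """Point-to-point muscle: cranium-fixed origin, mandible-fixed insertion (mm)."""

    name: str
    side: str  # 'left' | 'right'
    group: str  # one of MUSCLE_GROUPS
    origin: np.ndarray  # world, mm
    insertion: np.ndarray  # mandible frame, mm
    params: HillMuscleParams
    active: bool = True

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, float))
        if self.group not in MUSCLE_GROUPS:
            raise InvalidInputError(f"unknown muscle group {self.group!r}")


@dataclass(frozen=True)
class Ligament:
    name: str
    side: str
    origin: np.ndarray  # world (cranium), mm
    insertion: np.ndarray  # mandible frame, mm
    params: LigamentParams

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, float))


@dataclass(frozen=True)
class JointSite:
    """Condylar elastic-foundation contact site (sphere-in-socket), mm."""

    side: str
    sphere_center: np.ndarray  # mandible frame, mm
    sphere_radius: float
    socket_center: np.ndarray  # world, mm
    socket_radius: float
    ef: ElasticFoundationParams

    def __post_init__(self):
        object.__setattr__(self, "sphere_center", np.asarray(self.sphere_center, float))
        object.__setattr__(self, "socket_center", np.asarray(self.socket_center, float))
        if self.socket_radius < self.sphere_radius:
            raise InvalidInputError("socket radius must be >= sphere radius")


@dataclass(frozen=True)
class PlanarBiteConstraint:
    """Plane through the three bite landmarks; holds them on the plane.

    The normal is unit length and oriented superiorly (toward the
    cranium). Restricting three non-collinear body points to a plane
    removes the out-of-plane translation and both out-of-plane rotations.
    """

    point: np.ndarray  # on plane, world mm
    normal: np.ndarray  # unit, world
    landmarks: np.ndarray  # (3, 3) world mm: left premolar, right premolar, incisor

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, float))
        n = np.asarray(self.normal, float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))
        object.__setattr__(self, "landmarks", np.asarray(self.landmarks, float))


@dataclass(frozen=True)
class TrackingWeights:
    """Objective weights (w_d << w_a << w_c for a well-behaved tracker)."""

    w_c: float = 1.0
    w_a: float = 0.0025
    w_d: float = 0.00001

    def __post_init__(self):
        if min(self.w_c, self.w_a, self.w_d) < 0:
            raise InvalidInputError("weights must be non-negative")


@dataclass(frozen=True)
class MusculoskeletalModel:
    """Rigid mandible + muscles + ligaments + joint sites + bite landmarks.

    Positions in mm (mandible frame = world frame at the rest pose, origin
    at the center of mass); mass in kg, body-frame inertia diagonal in
    kg m^2. ``damping`` = (linear N s/m, angular N m s/rad) viscous terms
    giving the quasi-static character of a static clench.
    """

    mass: float
    inertia_diag: np.ndarray  # kg m^2, body frame
    com: np.ndarray  # world position of COM at rest, mm
    muscles: tuple[Muscle, ...]
    ligaments: tuple[Ligament, ...]
    joint_sites: tuple[JointSite, ...]
    bite_points: dict  # 'left_premolar', 'right_premolar', 'incisor' -> world mm
    condyle_tops: dict  # 'left', 'right' -> world mm
    menton: np.ndarray  # world mm
    task_side: str = "left"
    gravity: bool = True
    damping: tuple[float, float] = (150.0, 0.3)

    def __post_init__(self):
        object.__setattr__(self, "inertia_diag", np.asarray(self.inertia_diag, float))
        object.__setattr__(self, "com", np.asarray(self.com, float))
        object.__setattr__(self, "menton", np.asarray(self.menton, float))
        active = [m for m in self.muscles if m.active]
        for side in ("left", "right"):
            groups = sorted(m.group for m in active if m.side == side)
            if len(groups) != 6:
                raise InvalidInputError(f"{side} side must have six active muscles")
        if self.task_side not in ("left", "right"):
            raise InvalidInputError("task_side must be 'left' or 'right'")
        build_bite_plane(self.bite_points["left_premolar"],
                         self.bite_points["right_premolar"],
                         self.bite_points["incisor"])

    @property
    def active_muscles(self) -> list[Muscle]:
        return [m for m in self.muscles if m.active]

    def mandible_length(self) -> float:
        """Average condyle-top-to-menton distance, mm."""
        d_l = np.linalg.norm(self.condyle_tops["left"] - self.menton)
        d_r = np.linalg.norm(self.condyle_tops["right"] - self.menton)
        return 0.5 * (d_l + d_r)


@dataclass
class RigidBodyState:
    """Mandible pose and velocity (SI: m, m/s, rad/s; pose about the COM)."""

    x: np.ndarray  # COM position, m
    rot: np.ndarray  # 3x3 rotation, body -> world
    v: np.ndarray  # COM linear velocity, m/s
    w: np.ndarray  # angular velocity, rad/s

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.rot = np.asarray(self.rot, float)
        self.v = np.asarray(self.v, float)
        self.w = np.asarray(self.w, float)
        if np.linalg.norm(self.rot @ self.rot.T - np.eye(3)) > 1e-9:
            raise InvalidInputError("rotation not orthonormal")

    @staticmethod
    def rest(model: MusculoskeletalModel) -> "RigidBodyState":
        return RigidBodyState(x=model.com * MM, rot=np.eye(3),
                              v=np.zeros(3), w=np.zeros(3))

    def body_to_world_mm(self, p_body_mm: np.ndarray, model: MusculoskeletalModel) -> np.ndarray:
        """Map a rest-pose (mm) point through the current pose, result in mm."""
        b = (np.asarray(p_body_mm, float) - model.com) * MM
        return (self.x + self.rot @ b) / MM


@dataclass(frozen=True)
class ActivationVector:
    """Reduced activation variables plus the expansion to physical muscles.

    ``expand`` maps the free variables u to the per-muscle activations
    a = E u; bounds on u are tightened so the expansion stays in [0, 1].
    """

    values: np.ndarray
    expansion: np.ndarray  # (n_muscles, n_free)
    upper_bounds: np.ndarray
    labels: tuple[str, ...]

    @property
    def expanded(self) -> np.ndarray:
        a = self.expansion @ self.values
        if np.any(a < -1e-9) or np.any(a > 1.0 + 1e-9):
            raise InvalidInputError("expanded activation outside [0, 1]")
        return np.clip(a, 0.0, 1.0)


@dataclass
class SimulationResult:
    """Time histories and terminal summary of one bite-task simulation."""

    times: np.ndarray
    activations: np.ndarray  # (n_steps, n_active_muscles), expanded
    bite_force: np.ndarray  # achieved normal force at task premolar, N
    target_force: np.ndarray
    joint_force_left: np.ndarray  # (n_steps, 3), N
    joint_force_right: np.ndarray
    muscle_names: tuple[str, ...]
    task_side: str
    saturated: bool = False
    equilibrium_residual: tuple[float, float] = (np.nan, np.nan)  # (N, N mm)
    terminal_state: "RigidBodyState | None" = None

    @property
    def terminal_bite_force(self) -> float:
        return float(self.bite_force[-1])

    def terminal_joint_force(self, side: str) -> np.ndarray:
        return (self.joint_force_left if side == "left" else self.joint_force_right)[-1]


# ---------------------------------------------------------------------------
# operations

def build_bite_plane(premolar_left, premolar_right, incisor,
                     superior_hint=(0.0, 0.0, 1.0)) -> PlanarBiteConstraint:
    """Plane through the three bite landmarks, normal oriented superiorly."""
    p1 = np.asarray(premolar_left, float)
    p2 = np.asarray(premolar_right, float)
    p3 = np.asarray(incisor, float)
    n = np.cross(p2 - p1, p3 - p1)
    nrm = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if nrm < 1e-9 * scale ** 2:
        raise InvalidInputError("bite landmarks are collinear")
    n = n / nrm
    if np.dot(n, np.asarray(superior_hint, float)) < 0:
        n = -n
    return PlanarBiteConstraint(point=p1, normal=n,
                                landmarks=np.stack([p1, p2, p3]))


def _skew(r: np.ndarray) -> np.ndarray:
    return np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0.0]])


def _rodrigues(phi: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(phi)
    if theta < 1e-12:
        return np.eye(3) + _skew(phi)
    k = phi / theta
    kk = _skew(k)
    return np.eye(3) + np.sin(theta) * kk + (1 - np.cos(theta)) * (kk @ kk)


class _Assembled:
    """Cached SI-unit arrays derived from a model (created once per simulation)."""

    def __init__(self, model: MusculoskeletalModel):
        self.model = model
        com = model.com
        self.plane = build_bite_plane(model.bite_points["left_premolar"],
                                      model.bite_points["right_premolar"],
                                      model.bite_points["incisor"])
        self.n_w = self.plane.normal  # unit, dimensionless
        self.plane_point = self.plane.point * MM
        # body coordinates (m) relative to COM
        self.bite_body = (self.plane.landmarks - com) * MM
        self.task_idx = 0 if model.task_side == "left" else 1
        act = model.active_muscles
        self.muscles = act
        self.m_origin = np.array([m.origin for m in act]) * MM
        self.m_insert_body = np.array([(m.insertion - com) * MM for m in act])
        self.ligs = model.ligaments
        self.l_origin = np.array([l.origin for l in self.ligs]) * MM if self.ligs else np.zeros((0, 3))
        self.l_insert_body = (np.array([(l.insertion - com) * MM for l in self.ligs])
                              if self.ligs else np.zeros((0, 3)))
        self.sites = model.joint_sites
        self.s_center_body = np.array([(s.sphere_center - com) * MM for s in self.sites])
        self.s_socket = np.array([s.socket_center for s in self.sites]) * MM
        self.mgen = np.zeros((6, 6))
        self.mgen[:3, :3] = np.eye(3) * model.mass
        self.i_body = np.diag(model.inertia_diag)

    # ---- kinematics -----------------------------------------------------
    def point_world(self, state: RigidBodyState, body: np.ndarray) -> np.ndarray:
        return state.x + body @ state.rot.T

    # ---- forces ---------------------------------------------------------
    def muscle_geometry(self, state: RigidBodyState):
        ins = self.point_world(state, self.m_insert_body)
        d = self.m_origin - ins
        lengths = np.linalg.norm(d, axis=1)
        dirs = d / lengths[:, None]
        return ins, dirs, lengths

    def muscle_wrenches(self, state: RigidBodyState, unit: bool = False):
        """Per-muscle wrench (force, torque about COM) at unit activation.

        ``unit`` gives the active part only (the H_c perturbation); the
        passive part is returned separately by passive_wrench.
        """
        ins, dirs, lengths = self.muscle_geometry(state)
        out = np.zeros((len(self.muscles), 6))
        for j, m in enumerate(self.muscles):
            l_mm = lengths[j] / MM
            f_act = (hill_static_force(1.0, l_mm, m.params)
                     - hill_static_force(0.0, l_mm, m.params))
            f = f_act * dirs[j]
            out[j, :3] = f
            out[j, 3:] = np.cross(ins[j] - state.x, f)
        return out

    def passive_wrench(self, state: RigidBodyState) -> np.ndarray:
        """Ligaments + passive muscle + contact + gravity, about the COM."""
        w6 = np.zeros(6)
        ins, dirs, lengths = self.muscle_geometry(state)
        for j, m in enumerate(self.muscles):
            f_p = hill_static_force(0.0, lengths[j] / MM, m.params)
            if f_p > 0:
                f = f_p * dirs[j]
                w6[:3] += f
                w6[3:] += np.cross(ins[j] - state.x, f)
        if len(self.ligs):
            ins_l = self.point_world(state, self.l_insert_body)
            d = self.l_origin - ins_l
            lengths_l = np.linalg.norm(d, axis=1)
            for j, lig in enumerate(self.ligs):
                t = ligament_force(lengths_l[j] / MM, lig.params)
                if t > 0:
                    f = t * d[j] / lengths_l[j]
                    w6[:3] += f
                    w6[3:] += np.cross(ins_l[j] - state.x, f)
        forces, _, _ = self.contact_forces(state)
        centers = self.point_world(state, self.s_center_body)
        for k in range(len(self.sites)):
            w6[:3] += forces[k]
            w6[3:] += np.cross(centers[k] - state.x, forces[k])
        if self.model.gravity:
            w6[2] += -9.81 * self.model.mass
        return w6

    def contact_forces(self, state: RigidBodyState):
        """Per-site EF contact force on the mandible (N) + stiffness (N/m)."""
        centers = self.point_world(state, self.s_center_body)
        forces = np.zeros((len(self.sites), 3))
        stiffness = np.zeros(len(self.sites))
        dirs = np.zeros((len(self.sites), 3))
        for k, site in enumerate(self.sites):
            e_vec = (centers[k] - self.s_socket[k]) / MM  # mm
            e = np.linalg.norm(e_vec)
            mag = _ef_socket_force(e, site)
            if mag > 0.0:
                u = e_vec / e
                forces[k] = -mag * u
                dirs[k] = u
                de = 1e-5  # mm
                stiffness[k] = (_ef_socket_force(e + de, site) - mag) / (de * MM)
        return forces, dirs, stiffness

    # ---- constraint algebra --------------------------------------------
    def constraint_matrix(self, state: RigidBodyState):
        """G (3x6) rows [n, r_i x n] and current violations e (m)."""
        pts = self.point_world(state, self.bite_body)
        g = np.zeros((3, 6))
        e = np.zeros(3)
        for i in range(3):
            r = pts[i] - state.x
            g[i, :3] = self.n_w
            g[i, 3:] = np.cross(r, self.n_w)
            e[i] = np.dot(self.n_w, pts[i] - self.plane_point)
        return g, e

    def generalized_mass(self, state: RigidBodyState) -> np.ndarray:
        mgen = self.mgen.copy()
        i_w = state.rot @ self.i_body @ state.rot.T
        mgen[3:, 3:] = i_w
        return mgen

    def static_multipliers(self, state: RigidBodyState, w6: np.ndarray) -> np.ndarray:
        """Constraint reactions lambda for an applied wrench (N per landmark).

        Dynamically consistent projection: out-of-plane accelerations
        vanish, lambda = -(G M^-1 G^T)^-1 G M^-1 w6. Linear in the wrench.
        """
        g, _ = self.constraint_matrix(state)
        minv = np.linalg.inv(self.generalized_mass(state))
        gm = g @ minv
        return -np.linalg.solve(gm @ g.T, gm @ w6)

    def bite_force_of_wrench(self, state: RigidBodyState, w6: np.ndarray) -> float:
        """Normal force the task premolar exerts on the bite plane (N)."""
        lam = self.static_multipliers(state, w6)
        return -float(lam[self.task_idx])


def _ef_socket_force(e: float, site: JointSite) -> float:
    """Magnitude of the EF contact force for center offset e (mm) -> N.

    Gauss-Legendre quadrature of p(d) over the penetrating spherical cap;
    the resultant acts along the center-offset direction by symmetry.
    """
    clear = site.socket_radius - site.sphere_radius
    if e <= clear or e == 0.0:
        return 0.0
    r, rs = site.sphere_radius, site.socket_radius
    d0 = e - clear
    if d0 >= site.ef.thickness:
        raise PenetrationSaturationError(
            f"condylar penetration {d0:.4g} mm >= cartilage thickness "
            f"{site.ef.thickness} mm at {site.side} joint")
    # contact boundary: |q - s| = rs  ->  cos(theta_max)
    cos_max = (rs * rs - e * e - r * r) / (2.0 * e * r)
    cos_max = min(cos_max, 1.0)
    nodes, weights = np.polynomial.legendre.leggauss(24)
    u = 0.5 * (nodes + 1.0) * (1.0 - cos_max) + cos_max  # cos(theta) in [cos_max, 1]
    half_width = 0.5 * (1.0 - cos_max)
    rho = np.sqrt(e * e + r * r + 2.0 * e * r * u)
    d = rho - rs
    p = np.array([ef_pressure(max(di, 0.0), site.ef) for di in d])  # MPa
    axial = (e + r * u) / rho
    # integral over the cap: 2 pi r^2 int p * axial d(cos theta)
    return float(2.0 * np.pi * r * r * half_width * np.sum(weights * p * axial))


def excitation_response(model: MusculoskeletalModel, state: RigidBodyState,
                        assembled: _Assembled | None = None) -> np.ndarray:
    """H_c: bite-force output per unit activation, one column per active muscle.

    Column j is the normal bite force generated at the task-side premolar
    by muscle j at unit activation with every other activation zero and
    the current passive state subtracted; assembled by perturbation
    through the constraint-reaction projection, hence exactly linear in
    the activations at the current configuration.
    """
    asm = assembled or _Assembled(model)
    wrenches = asm.muscle_wrenches(state)
    h = np.array([asm.bite_force_of_wrench(state, w6) for w6 in wrenches])
    return h.reshape(1, -1)


def combine_pair_columns(col_ipsi: np.ndarray, col_contra: np.ndarray,
                         ratio: float) -> tuple[np.ndarray, float]:
    """Merge an (ipsi, contra) column pair under a_ipsi = r * a_contra.

    Returns the combined column r*ipsi + contra and the tightened upper
    bound min(1, 1/r) keeping both expanded activations in [0, 1].
    """
    if ratio <= 0:
        raise InvalidInputError("IC ratio must be positive")
    return ratio * np.asarray(col_ipsi, float) + np.asarray(col_contra, float), \
        min(1.0, 1.0 / ratio)


def impose_ic_ratios(h_c: np.ndarray, model: MusculoskeletalModel,
                     ratios: dict[str, float]) -> tuple[np.ndarray, ActivationVector]:
    """Reduce H_c by the measured temporalis/masseter IC ratios.

    Each left/right strand pair in the temporalis and masseter groups
    collapses to one free variable u with a_ipsi = r u, a_contra = u
    (ipsilateral defined by the model's task side); other muscles keep
    their own variable. Returns the reduced matrix and a template
    ActivationVector holding the expansion map and bounds.
    """
    for g, r in ratios.items():
        if r <= 0:
            raise InvalidInputError(f"IC ratio for {g} must be positive")
    act = model.active_muscles
    ipsi = model.task_side
    n = len(act)
    cols: list[np.ndarray] = []
    ubs: list[float] = []
    labels: list[str] = []
    used = np.zeros(n, dtype=bool)
    for j, m in enumerate(act):
        if used[j]:
            continue
        if m.group in ratios:
            # find the contralateral strand with the same name stem
            partner = next(k for k, o in enumerate(act)
                           if k != j and o.group == m.group
                           and o.name.split("_", 1)[-1] == m.name.split("_", 1)[-1])
            used[j] = used[partner] = True
            r = ratios[m.group]
            col = np.zeros(n)
            jp, jc = (j, partner) if m.side == ipsi else (partner, j)
            col[jp] = r
            col[jc] = 1.0
            cols.append(col)
            ubs.append(min(1.0, 1.0 / r))
            labels.append(f"{m.group}_{m.name.split('_', 1)[-1]}_pair")
        else:
            used[j] = True
            col = np.zeros(n)
            col[j] = 1.0
            cols.append(col)
            ubs.append(1.0)
            labels.append(m.name)
    expansion = np.stack(cols, axis=1)  # (n_muscles, n_free)
    template = ActivationVector(values=np.zeros(len(cols)), expansion=expansion,
                                upper_bounds=np.array(ubs), labels=tuple(labels))
    return np.asarray(h_c, float) @ expansion, template


def solve_tracking_step(h_red: np.ndarray, target: float, u_prev: np.ndarray,
                        weights: TrackingWeights, upper_bounds: np.ndarray,
                        expansion: np.ndarray | None = None) -> np.ndarray:
    """Exact solution of the per-step tracking QP (box-constrained BVLS).

    Regularization and damping act on the physical activations a = E u;
    pass ``expansion`` when the variables are IC-reduced (E = identity
    otherwise).
    """
    h = np.atleast_2d(np.asarray(h_red, float))
    u_prev = np.asarray(u_prev, float)
    ub = np.asarray(upper_bounds, float)
    if np.any(ub < 0):
        raise InvalidInputError("bounds must be non-negative")
    e_mat = np.eye(h.shape[1]) if expansion is None else np.asarray(expansion, float)
    rows = [np.sqrt(weights.w_c) * h]
    rhs = [np.sqrt(weights.w_c) * np.atleast_1d(target)]
    if weights.w_a > 0:
        rows.append(np.sqrt(weights.w_a) * e_mat)
        rhs.append(np.zeros(e_mat.shape[0]))
    if weights.w_d > 0:
        rows.append(np.sqrt(weights.w_d) * e_mat)
        rhs.append(np.sqrt(weights.w_d) * (e_mat @ u_prev))
    a_mat = np.vstack(rows)
    b_vec = np.concatenate(rhs)
    res = lsq_linear(a_mat, b_vec, bounds=(np.zeros_like(ub), ub),
                     method="bvls", tol=1e-14)
    if not res.success and res.status not in (2, 3):
        raise RuntimeError(f"tracking QP failed: {res.message}")
    return np.clip(res.x, 0.0, ub)


def tracking_kkt_residual(h_red, target, u_prev, weights, upper_bounds, u,
                          expansion=None) -> float:
    """Max violated KKT stationarity component of a candidate solution."""
    h = np.atleast_2d(np.asarray(h_red, float))
    e_mat = np.eye(h.shape[1]) if expansion is None else np.asarray(expansion, float)
    grad = (-weights.w_c * h.T @ (np.atleast_1d(target) - h @ u)
            + weights.w_a * e_mat.T @ (e_mat @ u)
            + weights.w_d * e_mat.T @ e_mat @ (u - u_prev))
    ub = np.asarray(upper_bounds, float)
    resid = np.where(u <= 1e-12, np.minimum(grad, 0.0),
                     np.where(u >= ub - 1e-12, np.maximum(grad, 0.0), grad))
    return float(np.abs(resid).max())


def joint_contact_force(model: MusculoskeletalModel, state: RigidBodyState,
                        assembled: _Assembled | None = None) -> dict[str, np.ndarray]:
    """Per-side contact force the mandible transmits through each joint (N)."""
    asm = assembled or _Assembled(model)
    forces, _, _ = asm.contact_forces(state)
    out = {"left": np.zeros(3), "right": np.zeros(3)}
    for k, site in enumerate(asm.sites):
        out[site.side] = out[site.side] + forces[k]
    return out


def step(model: MusculoskeletalModel, state: RigidBodyState,
         activations: np.ndarray, dt: float,
         assembled: _Assembled | None = None,
         constrained: bool = True) -> RigidBodyState:
    """One semi-implicit Euler step of the constrained 6-DOF dynamics.

    Contact and viscous damping are treated implicitly (linearized) for
    stability at the elastic-foundation stiffness; the planar constraint
    is enforced by Lagrange multipliers at the velocity level plus an
    exact position projection (residual < 1e-8 mm).
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    asm = assembled or _Assembled(model)
    a = np.asarray(activations, float)
    w6 = asm.passive_wrench(state)
    if len(a):
        w6 = w6 + asm.muscle_wrenches(state).T @ a
    i_w = state.rot @ asm.i_body @ state.rot.T
    w6[3:] -= np.cross(state.w, i_w @ state.w)  # gyroscopic

    mgen = asm.generalized_mass(state)
    c_lin, c_ang = model.damping
    d_mat = np.diag([c_lin] * 3 + [c_ang] * 3)
    k_mat = np.zeros((6, 6))
    forces, dirs, stiff = asm.contact_forces(state)
    centers = asm.point_world(state, asm.s_center_body)
    for k in range(len(asm.sites)):
        if stiff[k] > 0:
            jac = np.hstack([np.eye(3), -_skew(centers[k] - state.x)])
            k_mat += jac.T @ (stiff[k] * np.outer(dirs[k], dirs[k])) @ jac

    a_mat = mgen + dt * d_mat + dt * dt * k_mat
    rhs = mgen @ np.concatenate([state.v, state.w]) + dt * w6

    if constrained:
        g, e = asm.constraint_matrix(state)
        kkt = np.zeros((9, 9))
        kkt[:6, :6] = a_mat
        kkt[:6, 6:] = g.T
        kkt[6:, :6] = g
        sol = np.linalg.solve(kkt, np.concatenate([rhs, -e / dt]))
        v6 = sol[:6]
    else:
        v6 = np.linalg.solve(a_mat, rhs)

    x_new = state.x + dt * v6[:3]
    rot_new = _rodrigues(dt * v6[3:]) @ state.rot
    # re-orthonormalize
    u_svd, _, vt = np.linalg.svd(rot_new)
    rot_new = u_svd @ vt
    new = RigidBodyState(x=x_new, rot=rot_new, v=v6[:3], w=v6[3:])

    if constrained:
        for _ in range(6):
            g, e = asm.constraint_matrix(new)
            if np.abs(e).max() < 1e-8 * MM:
                break
            delta = g.T @ np.linalg.solve(g @ g.T, -e)
            new = RigidBodyState(x=new.x + delta[:3],
                                 rot=_rodrigues(delta[3:]) @ new.rot,
                                 v=new.v, w=new.w)
    return new


def simulate_task(model: MusculoskeletalModel, force_curve: UniformSeries,
                  ratios: dict[str, float],
                  weights: TrackingWeights = TrackingWeights(),
                  dt: float = 1e-3) -> SimulationResult:
    """Forward-dynamics force tracking of one unilateral bite task.

    Per step: assemble H_c at the current configuration, reduce by the IC
    ratios, solve the tracking QP warm-started from the previous step,
    expand the activations and integrate. The target is the force-curve
    sample at the step time; histories and the terminal equilibrium
    residual are recorded. An unreachable target marks the result
    ``saturated`` rather than raising.
    """
    if abs(force_curve.duration - 0.25) > force_curve.dt:
        raise InvalidInputError("force curve must span 0.25 s")
    asm = _Assembled(model)
    state = RigidBodyState.rest(model)
    targets = np.interp(np.arange(int(round(0.25 / dt))) * dt + dt,
                        force_curve.times, force_curve.values)
    n_steps = len(targets)
    n_act = len(asm.muscles)

    times = np.zeros(n_steps)
    acts = np.zeros((n_steps, n_act))
    bite = np.zeros(n_steps)
    jf_l = np.zeros((n_steps, 3))
    jf_r = np.zeros((n_steps, 3))
    saturated = False
    template = None
    u = None

    for i, cbar in enumerate(targets):
        h = excitation_response(model, state, asm)
        h_red, template = impose_ic_ratios(h, model, ratios)
        if u is None:
            u = np.zeros(template.expansion.shape[1])
        # the passive state (contact, ligaments, gravity) already produces a
        # bite-force offset; the muscles track the remainder
        bite_passive = asm.bite_force_of_wrench(state, asm.passive_wrench(state))
        u = solve_tracking_step(h_red, cbar - bite_passive, u, weights,
                                template.upper_bounds,
                                expansion=template.expansion)
        act = replace(template, values=u)
        a = act.expanded
        capacity = float((np.clip(h_red, 0.0, None) @ template.upper_bounds).item())
        if capacity < cbar - 0.02 * max(cbar, 1.0):
            saturated = True
        state = step(model, state, a, dt, asm)

        times[i] = (i + 1) * dt
        acts[i] = a
        w6 = asm.passive_wrench(state) + asm.muscle_wrenches(state).T @ a
        if model.gravity:
            pass  # gravity already inside passive_wrench
        bite[i] = asm.bite_force_of_wrench(state, w6)
        jf = joint_contact_force(model, state, asm)
        jf_l[i] = jf["left"]
        jf_r[i] = jf["right"]

    # terminal equilibrium residual: applied + constraint reactions
    w6 = asm.passive_wrench(state) + asm.muscle_wrenches(state).T @ acts[-1]
    lam = asm.static_multipliers(state, w6)
    g, _ = asm.constraint_matrix(state)
    resid = w6 + g.T @ lam
    force_res = float(np.linalg.norm(resid[:3]))
    torque_res = float(np.linalg.norm(resid[3:]) / MM)  # N m -> N mm

    return SimulationResult(times=times, activations=acts, bite_force=bite,
                            target_force=targets,
                            joint_force_left=jf_l, joint_force_right=jf_r,
                            muscle_names=tuple(m.name for m in asm.muscles),
                            task_side=model.task_side, saturated=saturated,
                            equilibrium_residual=(force_res, torque_res),
                            terminal_state=state)


def summarize_joint_loading(result: SimulationResult) -> dict[str, float]:
    """Terminal joint contact force per side as % of terminal bite force."""
    from .morphometrics import round_half_up

    bite = result.terminal_bite_force
    if bite <= 0:
        raise InvalidInputError("terminal bite force must be positive")
    out = {}
    for side in ("left", "right"):
        pct = 100.0 * float(np.linalg.norm(result.terminal_joint_force(side))) / bite
        out[side] = round_half_up(pct, 1)
    return out
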