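"""Mandible-length sweep: the force-tracking sanity check.

The normalized joint contact force (terminal joint force / bite force,
averaged over the two joints) is expected to vary approximately linearly
with the ratio of mandible length to the moment arm of the resultant
muscle force — the classic class-III-lever behavior of the masticatory
system. The sweep rescales the model's attachments along the
anterior-posterior axis in proportion to their distance from the
condyle-top plane, simulates each geometry, and fits a line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constitutive import hill_static_force
from .core import InvalidInputError, UniformSeries
from .simulator import (MusculoskeletalModel, RigidBodyState, TrackingWeights,
                        _Assembled, simulate_task)

DEFAULT_SWEEP_LENGTHS = tuple(float(x) for x in range(105, 140, 5))


@dataclass
class SweepRow:
    mandible_length: float  # mm
    moment_arm: float  # mm
    ratio: float  # length / moment arm
    normalized_joint_force: float  # mean bilateral |J| / bite
    failed: bool = False


@dataclass
class SweepResult:
    rows: list[SweepRow]
    slope: float
    intercept: float
    r_squared: float

    @property
    def ok_rows(self) -> list[SweepRow]:
        return [r for r in self.rows if not r.failed]


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares line fit with R^2 (degenerate-x rejected).

    A constant-y input has SS_tot = 0; R^2 is then reported as NaN
    (undefined) rather than dividing by zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size != x.size:
        raise InvalidInputError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate fit: x values all equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = np.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def rescale_mandible(model: MusculoskeletalModel, target_length: float) -> MusculoskeletalModel:
    """Rescale anterior-posterior geometry to the target mandible length.

    Every muscle and ligament attachment (both ends), bite landmark,
    menton and the center of mass move along the AP axis in proportion to
    their distance from the condyle-top plane; condyle positions and the
    joint-site geometry are preserved. The single scale factor is solved
    so the resulting average condyle-top-to-menton distance equals
    ``target_length`` exactly (a naive length ratio would miss because
    the menton also has lateral/vertical offsets from the condyles).
    """
    if target_length <= 0:
        raise InvalidInputError("target length must be positive")
    tops = model.condyle_tops
    y_ref = 0.5 * (tops["left"][1] + tops["right"][1])

    def length_for(s: float) -> float:
        m = model.menton.copy()
        m[1] = y_ref + s * (m[1] - y_ref)
        d_l = np.linalg.norm(tops["left"] - m)
        d_r = np.linalg.norm(tops["right"] - m)
        return 0.5 * (d_l + d_r)

    # closed-form solve for the symmetric case; bisection fallback otherwise
    from scipy.optimize import brentq
    if abs(length_for(1.0) - target_length) < 1e-12:
        s = 1.0
    else:
        s = brentq(lambda v: length_for(v) - target_length, 1e-3, 10.0,
                   xtol=1e-13, rtol=8.9e-16)

    def scale_pt(p: np.ndarray) -> np.ndarray:
        q = np.asarray(p, float).copy()
        q[1] = y_ref + s * (q[1] - y_ref)
        return q

    # attachments move; element rest lengths follow the new geometry so the
    # relative operating point is preserved (a rescaled model is a different
    # subject, not a pre-strained one)
    muscles = []
    for m in model.muscles:
        o, i = scale_pt(m.origin), scale_pt(m.insertion)
        ratio_len = np.linalg.norm(o - i) / np.linalg.norm(m.origin - m.insertion)
        params = replace(m.params,
                         optimal_length=m.params.optimal_length * ratio_len)
        muscles.append(replace(m, origin=o, insertion=i, params=params))
    ligaments = []
    for l in model.ligaments:
        o, i = scale_pt(l.origin), scale_pt(l.insertion)
        ratio_len = np.linalg.norm(o - i) / max(np.linalg.norm(l.origin - l.insertion), 1e-12)
        params = replace(l.params,
                         initial_length=l.params.initial_length * ratio_len)
        ligaments.append(replace(l, origin=o, insertion=i, params=params))
    muscles = tuple(muscles)
    ligaments = tuple(ligaments)
    bite_points = {k: scale_pt(v) for k, v in model.bite_points.items()}
    return replace(model, muscles=muscles, ligaments=ligaments,
                   bite_points=bite_points, menton=scale_pt(model.menton),
                   com=scale_pt(model.com))


def resultant_moment_arm(model: MusculoskeletalModel, activations: np.ndarray,
                         state: RigidBodyState | None = None) -> float:
    """Moment arm of the resultant muscle force about the condylar axis (mm).

    The resultant is the vector sum of all active-muscle forces at the
    given activations, anchored at the force-weighted centroid of the
    insertion points; the moment arm is the perpendicular distance from
    the inter-condylar axis to its line of action. Clench displacements
    are sub-0.1 mm, so the rest pose is an adequate default state.
    """
    asm = _Assembled(model)
    st = state or RigidBodyState.rest(model)
    ins, dirs, lengths = asm.muscle_geometry(st)
    a = np.asarray(activations, float)
    if a.shape != (len(asm.muscles),):
        raise InvalidInputError("one activation per active muscle required")
    if not np.any(a > 0):
        raise InvalidInputError("at least one nonzero activation required")
    mags = np.array([hill_static_force(a[j], lengths[j] * 1e3, m.params)
                     for j, m in enumerate(asm.muscles)])
    forces = mags[:, None] * dirs
    f_tot = forces.sum(axis=0)
    f_norm = np.linalg.norm(f_tot)
    if f_norm <= 0:
        raise InvalidInputError("zero resultant muscle force")
    weights = mags / mags.sum()
    anchor = (weights[:, None] * ins).sum(axis=0)  # m

    c_left = np.array([s.sphere_center for s in model.joint_sites
                       if s.side == "left"])[0] * 1e-3
    c_right = np.array([s.sphere_center for s in model.joint_sites
                        if s.side == "right"])[0] * 1e-3
    axis_dir = (c_right - c_left)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    u2 = f_tot / f_norm
    cross = np.cross(axis_dir, u2)
    if np.linalg.norm(cross) < 1e-12:  # parallel lines
        d = np.linalg.norm(np.cross(anchor - c_left, axis_dir))
    else:
        d = abs(np.dot(anchor - c_left, cross)) / np.linalg.norm(cross)
    return float(d / 1e-3)  # m -> mm


def run_sweep(model: MusculoskeletalModel, lengths=DEFAULT_SWEEP_LENGTHS,
              force_curve: UniformSeries | None = None,
              ratios: dict[str, float] | None = None,
              weights: TrackingWeights = TrackingWeights(),
              dt: float = 1e-3) -> SweepResult:
    """Simulate each rescaled geometry and fit normalized joint force vs ratio."""
    from .synthetic import ramp_hold_curve

    lengths = [float(x) for x in lengths]
    if any(l2 <= l1 for l1, l2 in zip(lengths, lengths[1:])):
        raise InvalidInputError("lengths must be strictly increasing")
    if any(not (90.0 <= x <= 150.0) for x in lengths):
        warnings.warn("sweep length outside the physiologic 90-150 mm band")
    curve = force_curve or ramp_hold_curve()
    ratios = ratios or {"temporalis": 1.0, "masseter": 1.0}

    rows: list[SweepRow] = []
    for length in lengths:
        try:
            m = rescale_mandible(model, length)
            res = simulate_task(m, curve, ratios, weights=weights, dt=dt)
            bite = res.terminal_bite_force
            nj = 0.5 * (np.linalg.norm(res.terminal_joint_force("left"))
                        + np.linalg.norm(res.terminal_joint_force("right"))) / bite
            arm = resultant_moment_arm(m, res.activations[-1])
            rows.append(SweepRow(length, arm, length / arm, float(nj)))
        except Exception:
            rows.append(SweepRow(length, np.nan, np.nan, np.nan, failed=True))

    ok = [r for r in rows if not r.failed]
    if len(ok) >= 3:
        slope, intercept, r2 = linear_fit([r.ratio for r in ok],
                                          [r.normalized_joint_force for r in ok])
    else:
        slope = intercept = r2 = np.nan
    return SweepResult(rows=rows, slope=slope, intercept=intercept, r_squared=r2)
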