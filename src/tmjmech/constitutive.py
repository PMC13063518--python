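"""Material and element laws of the joint model.

Elastic-foundation (EF) contact for the articular cartilage layers,
incompressible Mooney-Rivlin (disc) and Neo-Hookean (capsule) strain
energies, tension-only cable ligaments with slack lengths, and static
Hill-type point-to-point muscle force.

The EF law gives contact pressure as a function of penetration d into a
thin compliant layer of thickness h:

    p(d) = K ln(1 - d/h),   K = -(1 - nu) E / ((1 + nu)(1 - 2 nu))

so p(0) = 0 and p grows without bound as d -> h (the layer bottoms out).
Energies are evaluated only on isochoric deformations (det F = 1); no
volumetric term is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import InvalidInputError


class PenetrationSaturationError(RuntimeError):
    """Penetration reached the cartilage thickness (EF law undefined)."""


@dataclass(frozen=True)
class ElasticFoundationParams:
    """Cartilage EF layer: thickness h (mm), modulus E (MPa), Poisson nu."""

    thickness: float = 0.4
    elastic_modulus: float = 2.7
    poisson: float = 0.49

    def __post_init__(self) -> None:
        if not (0.0 < self.poisson < 0.5):
            raise InvalidInputError("Poisson ratio must lie in (0, 0.5)")
        if self.thickness <= 0 or self.elastic_modulus <= 0:
            raise InvalidInputError("thickness and modulus must be positive")

    @property
    def stiffness(self) -> float:
        """K in MPa (negative; the log factor is negative too)."""
        nu, e = self.poisson, self.elastic_modulus
        return -(1.0 - nu) * e / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class MooneyRivlinParams:
    c1: float = 0.9   # MPa
    c2: float = 0.0009  # MPa

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise InvalidInputError("C1 must be positive")


@dataclass(frozen=True)
class NeoHookeanParams:
    c1: float = 1.44  # MPa

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise InvalidInputError("C1 must be positive")


@dataclass(frozen=True)
class LigamentParams:
    """Tension-only elastic cable.

    ``stiffness`` is in N per unit strain; strain is referenced to the
    slack-inclusive rest length L0 = initial_length + slack_length.
    """

    stiffness: float
    initial_length: float
    slack_length: float = 0.0

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise InvalidInputError("stiffness must be non-negative")
        if self.initial_length < 0 or self.slack_length < 0:
            raise InvalidInputError("lengths must be non-negative")
        if self.rest_length == 0 and self.stiffness > 0:
            raise InvalidInputError("zero rest length with positive stiffness")

    @property
    def rest_length(self) -> float:
        return self.initial_length + self.slack_length


def _default_active_fl(l_norm: np.ndarray) -> np.ndarray:
    """Parabolic active force-length curve, peak 1 at optimal length."""
    return np.maximum(0.0, 1.0 - ((l_norm - 1.0) / 0.5) ** 2)


def _default_passive_fp(l_norm: np.ndarray) -> np.ndarray:
    """Quadratic passive curve, zero at/below optimal length."""
    return np.where(l_norm > 1.0, (np.maximum(l_norm - 1.0, 0.0) / 0.5) ** 2, 0.0)


@dataclass(frozen=True)
class HillMuscleParams:
    """Static Hill-type point-to-point muscle.

    Clenching tasks are quasi-static, so the force-velocity factor is
    unity and F = F_max (a f_l(l/l_opt) + f_p(l/l_opt)). The curve shapes
    are configurable; defaults are a parabolic active curve of half-width
    0.5 l_opt and a quadratic passive curve engaging beyond l_opt.
    """

    max_isometric_force: float
    optimal_length: float
    active_curve: Callable[[np.ndarray], np.ndarray] = field(default=_default_active_fl)
    passive_curve: Callable[[np.ndarray], np.ndarray] = field(default=_default_passive_fp)

    def __post_init__(self) -> None:
        if self.max_isometric_force <= 0 or self.optimal_length <= 0:
            raise InvalidInputError("F_max and optimal length must be positive")


def ef_pressure(penetration: float, params: ElasticFoundationParams) -> float:
    """EF contact pressure in MPa; 0 for open contact (d < 0)."""
    d = float(penetration)
    if d < 0:
        return 0.0
    h = params.thickness
    if d >= h:
        raise PenetrationSaturationError(
            f"penetration {d:.4g} mm >= cartilage thickness {h} mm")
    return params.stiffness * np.log(1.0 - d / h)


def _invariants(f_mat: np.ndarray) -> tuple[float, float, float]:
    f = np.asarray(f_mat, dtype=float)
    if f.shape != (3, 3):
        raise InvalidInputError("deformation gradient must be 3x3")
    b = f @ f.T
    i1 = float(np.trace(b))
    i2 = 0.5 * float(np.trace(b) ** 2 - np.trace(b @ b))
    return i1, i2, float(np.linalg.det(f))


def mooney_rivlin_energy(f_mat: np.ndarray, params: MooneyRivlinParams,
                         det_tol: float = 1e-6) -> float:
    """W = C1 (I1 - 3) + C2 (I2 - 3), isochoric F only (MPa)."""
    i1, i2, det = _invariants(f_mat)
    if abs(det - 1.0) > det_tol:
        raise InvalidInputError(f"det F = {det:.8f} is not isochoric")
    return params.c1 * (i1 - 3.0) + params.c2 * (i2 - 3.0)


def neo_hookean_energy(f_mat: np.ndarray, params: NeoHookeanParams,
                       det_tol: float = 1e-6) -> float:
    """W = C1 (I1 - 3), isochoric F only (MPa)."""
    i1, _, det = _invariants(f_mat)
    if abs(det - 1.0) > det_tol:
        raise InvalidInputError(f"det F = {det:.8f} is not isochoric")
    return params.c1 * (i1 - 3.0)


def mr_uniaxial_stress(stretch: float, params: MooneyRivlinParams) -> float:
    """Closed-form incompressible uniaxial Cauchy stress (MPa).

    sigma = 2 (lambda^2 - 1/lambda)(C1 + C2/lambda); serves as the
    independent oracle for the energy implementation via dW/dlambda.
    """
    lam = float(stretch)
    if lam <= 0:
        raise InvalidInputError("stretch must be positive")
    return 2.0 * (lam ** 2 - 1.0 / lam) * (params.c1 + params.c2 / lam)


def ligament_force(current_length: float, params: LigamentParams) -> float:
    """Cable tension in N: stiffness * max(0, strain past rest length)."""
    length = float(current_length)
    if length < 0:
        raise InvalidInputError("length must be non-negative")
    l0 = params.rest_length
    if l0 == 0:
        return 0.0
    return params.stiffness * max(0.0, (length - l0) / l0)


def hill_static_force(activation: float, current_length: float,
                      params: HillMuscleParams) -> float:
    """Static Hill-type force in N at the given activation and length."""
    a = float(activation)
    if not (0.0 <= a <= 1.0):
        raise InvalidInputError("activation must lie in [0, 1]")
    l_norm = np.asarray(float(current_length) / params.optimal_length)
    f = params.max_isometric_force * (
        a * float(params.active_curve(l_norm)) + float(params.passive_curve(l_norm)))
    return max(0.0, f)
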