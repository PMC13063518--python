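"""Landmark-based morphometrics and the scaling-stress normalization.

Condylar areas (major x minor axis product), biting arms (premolar tip to
condyle top), intra-observer mean radial error of repeated landmark
selections, and the scaling stress (unilateral bite force / condylar
area, N/mm^2 = MPa) that normalizes all disc-stress comparisons across
subjects and pre/post-operative states.

Raw values are kept at full precision; the printed-table rounding (1
decimal for morphometric differences, 2 decimals for scaling stresses)
is applied only at the reporting layer, half-up.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, fields

import numpy as np

from .core import InvalidInputError

MORPHO_FIELDS = ("lca", "rca", "liba", "lcba", "riba", "rcba")


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class LandmarkSelectionSet:
    """Repeated selections of one anatomical landmark (>= 1 repetition, mm)."""

    name: str
    selections: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.selections, dtype=float))
        if pts.size == 0 or pts.shape[0] < 1:
            raise InvalidInputError(f"landmark {self.name!r}: no selections")
        if pts.ndim != 2 or pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
            raise InvalidInputError(f"landmark {self.name!r}: selections must be finite 3D points")
        object.__setattr__(self, "selections", pts)


@dataclass(frozen=True)
class MorphoMeasurements:
    """Condylar areas (mm^2) and biting arms (mm) for one case.

    lca/rca: left/right condylar area; liba/lcba: left-biting ipsi- and
    contralateral arms; riba/rcba: right-biting ipsi- and contralateral arms.
    """

    lca: float
    rca: float
    liba: float
    lcba: float
    riba: float
    rcba: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise InvalidInputError(f"{f.name} must be positive")


@dataclass(frozen=True)
class ScalingStress:
    """Bite force (N) over condylar area (mm^2), in MPa."""

    bite_force: float
    condylar_area: float

    @property
    def value(self) -> float:
        return self.bite_force / self.condylar_area

    @property
    def rounded(self) -> float:
        return round_half_up(self.value, 2)


def average_landmark(sel: LandmarkSelectionSet) -> np.ndarray:
    """Centroid of the repeated selections (selection-error reduction)."""
    return sel.selections.mean(axis=0)


def mean_radial_error(sets: list[LandmarkSelectionSet]) -> float:
    """Mean Euclidean deviation of each selection from its set centroid.

    The global mean pools every individual selection across all sets.
    """
    if not sets:
        raise InvalidInputError("no landmark sets given")
    devs = []
    for s in sets:
        if s.selections.shape[0] < 2:
            raise InvalidInputError(f"landmark {s.name!r}: MRE needs >= 2 selections")
        c = average_landmark(s)
        devs.append(np.linalg.norm(s.selections - c, axis=1))
    return float(np.concatenate(devs).mean())


def biting_arm(premolar_tip: np.ndarray, condyle_top: np.ndarray) -> float:
    """Euclidean distance first-premolar tip -> condyle top, in mm."""
    p = np.asarray(premolar_tip, float)
    c = np.asarray(condyle_top, float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(c))):
        raise InvalidInputError("landmarks must be finite")
    return float(np.linalg.norm(p - c))


def condylar_area(major_axis: float, minor_axis: float) -> float:
    """Condylar area approximated as major x minor axis product (mm^2)."""
    if major_axis <= 0 or minor_axis <= 0:
        raise InvalidInputError("axes must be positive")
    return float(major_axis) * float(minor_axis)


def scaling_stress(bite_force: float, condylar_area_mm2: float) -> ScalingStress:
    """Scaling stress = bite force / condylar area."""
    if condylar_area_mm2 <= 0:
        raise InvalidInputError("condylar area must be positive")
    if bite_force < 0:
        raise InvalidInputError("bite force must be non-negative")
    return ScalingStress(bite_force=float(bite_force), condylar_area=float(condylar_area_mm2))


def difference_table(case: MorphoMeasurements, reference: MorphoMeasurements,
                     rounded: bool = True) -> dict[str, float]:
    """Per-field ``case - reference`` differences (1-decimal rounding for tables)."""
    out = {}
    for name in MORPHO_FIELDS:
        d = getattr(case, name) - getattr(reference, name)
        out[name] = round_half_up(d, 1) if rounded else d
    return out
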