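"""Measured study-case inputs: function-assessment results and morphometrics.

Three subjects spanning the skeletal classes (Class I volunteer, Class II
patient pre/post BSSO advancement, Class III patient pre/post Le Fort I +
BSSO setback). For each case and biting side: the measured IC temporalis
and masseter ratios and the final bite force (N) from the function
assessment, plus the six morphometric measurements (condylar areas in
mm^2, biting arms in mm). These serve as model inputs and as the basis
for the scaling-stress normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

from .morphometrics import MorphoMeasurements, ScalingStress, scaling_stress

CASE_NAMES = ("class1", "class2_preop", "class2_postop", "class3_preop", "class3_postop")


@dataclass(frozen=True)
class TaskMeasurement:
    """Measured inputs of one unilateral bite task."""

    ic_temporalis: float
    ic_masseter: float
    final_bite_force: float  # N


@dataclass(frozen=True)
class CaseRecord:
    name: str
    left: TaskMeasurement
    right: TaskMeasurement
    morpho: MorphoMeasurements


CASES: dict[str, CaseRecord] = {
    "class1": CaseRecord(
        name="class1",
        left=TaskMeasurement(1.52, 1.43, 51.73),
        right=TaskMeasurement(0.71, 1.33, 48.43),
        morpho=MorphoMeasurements(lca=119.1, rca=91.0, liba=82.2, lcba=103.8,
                                  riba=83.6, rcba=99.3),
    ),
    "class2_preop": CaseRecord(
        name="class2_preop",
        left=TaskMeasurement(1.75, 1.69, 29.10),
        right=TaskMeasurement(0.62, 0.34, 39.20),
        morpho=MorphoMeasurements(lca=113.8, rca=147.5, liba=76.2, lcba=94.6,
                                  riba=74.3, rcba=92.6),
    ),
    "class2_postop": CaseRecord(
        name="class2_postop",
        left=TaskMeasurement(1.07, 0.97, 56.36),
        right=TaskMeasurement(0.61, 1.57, 54.35),
        morpho=MorphoMeasurements(lca=112.3, rca=109.0, liba=80.7, lcba=100.1,
                                  riba=82.2, rcba=97.5),
    ),
    "class3_preop": CaseRecord(
        name="class3_preop",
        left=TaskMeasurement(0.96, 1.34, 49.22),
        right=TaskMeasurement(0.41, 1.07, 35.16),
        morpho=MorphoMeasurements(lca=135.7, rca=150.7, liba=94.7, lcba=113.9,
                                  riba=94.4, rcba=111.1),
    ),
    "class3_postop": CaseRecord(
        name="class3_postop",
        left=TaskMeasurement(0.69, 0.71, 72.26),
        right=TaskMeasurement(1.37, 1.00, 61.85),
        morpho=MorphoMeasurements(lca=137.1, rca=141.8, liba=88.7, lcba=109.6,
                                  riba=90.4, rcba=106.3),
    ),
}


def scaling_stress_table(cases: dict[str, CaseRecord] = CASES) -> dict[str, dict[str, ScalingStress]]:
    """All scaling stresses: per case, biting side x disc side.

    Keys of the inner dict: ``left_bite_left_disc``, ``left_bite_right_disc``,
    ``right_bite_left_disc``, ``right_bite_right_disc``.
    """
    out: dict[str, dict[str, ScalingStress]] = {}
    for name, rec in cases.items():
        out[name] = {
            "left_bite_left_disc": scaling_stress(rec.left.final_bite_force, rec.morpho.lca),
            "left_bite_right_disc": scaling_stress(rec.left.final_bite_force, rec.morpho.rca),
            "right_bite_left_disc": scaling_stress(rec.right.final_bite_force, rec.morpho.lca),
            "right_bite_right_disc": scaling_stress(rec.right.final_bite_force, rec.morpho.rca),
        }
    return out
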