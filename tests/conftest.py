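"""Shared fixtures.

Simulations are the expensive fixtures, so the default toy-mandible
tasks are run once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmjmech import simulator, synthetic

CLASS1_LEFT_RATIOS = {"temporalis": 1.52, "masseter": 1.43}


@pytest.fixture(scope="session")
def toy_model():
    return synthetic.gen_toy_mandible()


@pytest.fixture(scope="session")
def force_curve_50():
    return synthetic.ramp_hold_curve(50.0)


@pytest.fixture(scope="session")
def class1_left_result(toy_model, force_curve_50):
    """Left unilateral 50 N clench with the Class-I left-bite IC ratios."""
    return simulator.simulate_task(toy_model, force_curve_50, CLASS1_LEFT_RATIOS)


@pytest.fixture(scope="session")
def coupled_symmetric_result(toy_model, force_curve_50):
    """All three muscle groups coupled left-right at unit ratio."""
    ratios = {"temporalis": 1.0, "masseter": 1.0, "medial_pterygoid": 1.0}
    return simulator.simulate_task(toy_model, force_curve_50, ratios)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
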