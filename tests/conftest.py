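"""Shared fixtures: the default acquisition schedule, a ground-truth
synthetic input function with its consistent blood fixture, and the
published grey-matter parameter sets used as recovery truths."""

import numpy as np
import pytest

from petkin import (
    FrameSchedule,
    KineticParams,
    SyntheticIFParams,
    gen_input_function,
)

#: Grey-matter 2TCM constants, subject 1 / test scan of the published study.
SUBJECT1_GM_2TCM = KineticParams(k1=0.094, k2=0.264, k3=0.076, k4=0.067)
#: Grey-matter 1TCM constants, subject 1 / test scan.
SUBJECT1_GM_1TCM = KineticParams(k1=0.074, k2=0.116)
#: Published grey-matter test-scan group means.
GM_MEAN_2TCM = KineticParams(k1=0.072, k2=0.237, k3=0.055, k4=0.029)


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def if_truth():
    return SyntheticIFParams()


@pytest.fixture(scope="session")
def aif_and_blood(schedule, if_truth):
    """Ground-truth input function (with bolus-shift headroom) and the
    blood fixture that reconstructs it."""
    return gen_input_function(if_truth, schedule.end_s + 120.0, schedule=schedule)


@pytest.fixture(scope="session")
def aif(aif_and_blood):
    return aif_and_blood[0]


@pytest.fixture(scope="session")
def blood(aif_and_blood):
    return aif_and_blood[1]


def draw_admissible_params(rng: np.random.Generator) -> KineticParams:
    """Random admissible two-tissue parameters spanning the bound range."""
    k1 = rng.uniform(0.02, 0.9)
    k2 = rng.uniform(0.02, 0.9)
    k3 = rng.uniform(0.005, 0.9)
    k4 = rng.uniform(0.005, 0.9)
    return KineticParams(k1=k1, k2=k2, k3=k3, k4=k4)


def max_rel_dev(a: np.ndarray, b: np.ndarray, floor_frac: float = 1e-9) -> float:
    """Max |a-b|/|b| with an absolute floor tied to the curve scale, so
    identically-zero pre-bolus frames do not produce 0/0."""
    b = np.asarray(b, dtype=float)
    floor = floor_frac * np.max(np.abs(b))
    denom = np.maximum(np.abs(b), floor if floor > 0 else 1.0)
    return float(np.max(np.abs(np.asarray(a) - b) / denom))
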