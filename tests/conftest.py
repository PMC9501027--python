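"""Shared fixtures: default curves, schedules, and a small noiseless phantom."""

from __future__ import annotations

import numpy as np
import pytest

from dynpet.kinetics_sim import (
    DEFAULT_LIVER_KINETICS,
    InputFunctionParams,
    PlasmaInputFunction,
    TissueKinetics,
    build_phantom,
    make_study_schedule,
)


@pytest.fixture(scope="session")
def if_params() -> InputFunctionParams:
    return InputFunctionParams()


@pytest.fixture(scope="session")
def cp_fine(if_params) -> PlasmaInputFunction:
    return PlasmaInputFunction.from_params(if_params, t_end=70.0)


@pytest.fixture(scope="session")
def study_schedule():
    return make_study_schedule(5, 11, 5, 35)


@pytest.fixture(scope="session")
def default_truth() -> dict[int, TissueKinetics]:
    return {
        1: TissueKinetics.macro(Ki=0.0, Vd=1.0),
        2: DEFAULT_LIVER_KINETICS,
        3: TissueKinetics.macro(Ki=0.030, Vd=0.9),
        4: TissueKinetics.macro(Ki=0.020, Vd=0.7),
    }


@pytest.fixture(scope="session")
def small_phantom(if_params, study_schedule, default_truth):
    """Noiseless 24^3 phantom with aorta, micro-kinetics liver, two macro lesions."""
    return build_phantom(
        (24, 24, 24), 6.0, default_truth, if_params, study_schedule,
        noise_scale=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def macro_phantom(if_params, study_schedule):
    """Tiny phantom whose liver and lesions are all exact macro tissues."""
    truth = {
        1: TissueKinetics.macro(Ki=0.0, Vd=1.0),
        2: TissueKinetics.macro(Ki=0.010, Vd=1.1),
        3: TissueKinetics.macro(Ki=0.030, Vd=0.9),
    }
    return build_phantom(
        (16, 16, 16), 9.0, truth, if_params, study_schedule,
        noise_scale=0.0, seed=5,
    )
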