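"""Shared fixtures: the published median parameter set of the selected
model (3C) and synthetic study-day datasets built from it."""

from __future__ import annotations

import logging

import pytest

from ipinsulin import (
    AbsorptionParams,
    FitConfig,
    KineticsParams,
    ModelSpec,
    PriorSpec,
    VirtualSubject,
    build_open_loop_design,
    fit_map,
    generate_dataset,
)

logging.getLogger("ipinsulin").setLevel(logging.ERROR)

#: Median kinetics of the selected model: VI 3.4 L, m1 0.15 min^-1,
#: CL 1.16 L/min, HEb 0.59, aI 16e-5 mU^-1 (m2 fixed at 0.268 min^-1).
MEDIAN_KINETICS = dict(VI=3.4, m1=0.15, CL=1.16, HEb=0.59, aI=16e-5)

#: Median per-meal absorption rates (breakfast, lunch, dinner).
MEDIAN_KA1 = (0.018, 0.004, 0.012)
MEDIAN_KA2 = (0.028, 0.028, 0.024)


@pytest.fixture(scope="session")
def median_kinetics() -> KineticsParams:
    return KineticsParams(**MEDIAN_KINETICS)


@pytest.fixture(scope="session")
def median_absorption() -> list[AbsorptionParams]:
    return [AbsorptionParams(ka1=a, ka2=b) for a, b in zip(MEDIAN_KA1, MEDIAN_KA2)]


@pytest.fixture(scope="session")
def model_3c() -> ModelSpec:
    return ModelSpec.from_string("3C")


@pytest.fixture(scope="session")
def open_loop_design():
    """0.60 U/kg/day for 75 kg, half basal, three equal meal boluses."""
    return build_open_loop_design(0.60, 75.0)


@pytest.fixture(scope="session")
def median_subject(median_kinetics, median_absorption) -> VirtualSubject:
    return VirtualSubject(kinetics=median_kinetics, absorption=tuple(median_absorption))


@pytest.fixture(scope="session")
def noise_free_day(median_subject, model_3c, open_loop_design):
    """Noise-free 24-h study day sampled every 10 min (145 samples)."""
    return generate_dataset(median_subject, model_3c, open_loop_design, cv=0.0, seed=0)


@pytest.fixture(scope="session")
def truth_centered_priors() -> PriorSpec:
    return PriorSpec.for_kinetics(3.4, 0.15, 1.16, 0.59, cv=1.0)


@pytest.fixture(scope="session")
def noise_free_fit(model_3c, noise_free_day, truth_centered_priors):
    """MAP fit of the generating model to its own noise-free output with
    priors centered at truth (estimator self-consistency reference)."""
    return fit_map(model_3c, noise_free_day, truth_centered_priors, FitConfig(restarts=1, seed=0))
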