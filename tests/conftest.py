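"""Shared fixtures: small seeded synthetic studies and converged fits."""

from __future__ import annotations

import numpy as np
import pytest

from evkinetics.nlme_engine import FitConfig, PopulationModel, fit, initial_estimates
from evkinetics.pk_model import DoseEvent, ModelSpec, StructuralParams
from evkinetics.synthetic_data import (
    DEFAULT_ARM_PARAMS,
    ArmDesign,
    StudyDesign,
    generate_study,
)

#: Clone 9 (liver hepatocyte EV) population estimates used as truths.
CLONE9 = StructuralParams(v1=28.0, v2=3057.0, v3=16.0, cl=(193.0,), cl2=111.0, cl3=21.0)
THREE_CPT = ModelSpec()
DOSE = DoseEvent(amount=2000.0)


@pytest.fixture(scope="session")
def clone9_params() -> StructuralParams:
    return CLONE9


@pytest.fixture(scope="session")
def three_cpt_spec() -> ModelSpec:
    return THREE_CPT


@pytest.fixture(scope="session")
def small_study():
    """Six clone-9 animals, seeded; fast enough for repeated fitting."""
    design = StudyDesign(arms={"clone9": ArmDesign(6, CLONE9)})
    data, truth = generate_study(design, seed=42)
    return data, truth


@pytest.fixture(scope="session")
def fitted_small(small_study):
    """Converged 3-compartment fit of the small study (with standard errors)."""
    data, _ = small_study
    theta0 = initial_estimates(data, THREE_CPT)
    model0 = PopulationModel(
        spec=THREE_CPT,
        theta=theta0,
        omega={"v1": 0.1, "v2": 0.1, "cl": 0.1},
        sigma=0.3,
        residual="log_additive",
    )
    result = fit(data, model0, FitConfig())
    assert result.converged
    return result


@pytest.fixture(scope="session")
def two_arm_study():
    """Two arms with a genuine cell-line difference on V2 (clone 9 vs RMC-like)."""
    alt = StructuralParams(v1=28.0, v2=752.0, v3=16.0, cl=(193.0,), cl2=111.0, cl3=21.0)
    design = StudyDesign(arms={"clone9": ArmDesign(5, CLONE9), "RMC": ArmDesign(5, alt)})
    return generate_study(design, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
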