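import numpy as np
import pytest

from crcsurv import (
    CohortScenario,
    DiseaseProgressionParams,
    LifeExpectancies,
    LocalStatus,
    MetStatus,
    RecurrenceSite,
    SurveillanceSchedule,
    TestCharacteristics,
    Modality,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240408)


@pytest.fixture
def calibrated_params():
    return DiseaseProgressionParams(
        r_d=0.092, x_du=6.0, r_u=0.11, x_ds=17.0, r_s=0.07, sigma_ds=11.0, m=0.016
    )


@pytest.fixture
def local_site():
    return RecurrenceSite(local_status=LocalStatus.LOCOREGIONAL)


@pytest.fixture
def liver_site():
    return RecurrenceSite(met_status=MetStatus.LIVER)


def make_scenario(
    n_patients=100,
    p_recur=0.4,
    progression=None,
    tests=(),
    schedule=None,
    horizon=20,
    site_dist=None,
    life_expectancies=None,
):
    """Small scenario factory used across test modules."""
    if progression is None:
        progression = DiseaseProgressionParams(
            r_d=0.092, x_du=6.0, r_u=0.11, x_ds=17.0, r_s=0.07, sigma_ds=11.0, m=0.016
        )
    if site_dist is None:
        site_dist = {
            RecurrenceSite(local_status=LocalStatus.LOCOREGIONAL): 0.5,
            RecurrenceSite(met_status=MetStatus.LIVER): 0.3,
            RecurrenceSite(met_status=MetStatus.MULTIPLE_OTHER): 0.2,
        }
    return CohortScenario(
        n_patients=n_patients,
        p_recur=p_recur,
        site_distribution=site_dist,
        progression=progression,
        tests=list(tests),
        schedule=schedule,
        life_expectancies=life_expectancies or LifeExpectancies(),
        horizon_cycles=horizon,
    )


def every_cycle_schedule(modalities, horizon=20):
    return SurveillanceSchedule(
        modalities=tuple(modalities),
        matrix=np.ones((horizon, len(modalities)), dtype=np.int8),
    )


def perfect_test(modality=Modality.CEA):
    return TestCharacteristics(modality=modality, sensitivity=1.0, specificity=1.0)


class FixedRng:
    """Deterministic stand-in for a Generator: returns preset draws in order."""

    def __init__(self, uniforms=(), normals=()):
        self._uniforms = list(uniforms)
        self._normals = list(normals)

    def uniform(self, *args, **kwargs):
        return self._uniforms.pop(0)

    def normal(self, loc=0.0, scale=1.0):
        # preset draws are taken verbatim (already on the target scale)
        return self._normals.pop(0)

    def exponential(self, scale=1.0):
        return scale * self._uniforms.pop(0)
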