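import numpy as np
import pytest

from caspopk.pk_core import Covariates, PKParameters, Regimen, concentration_profile
from caspopk.popfit import ErrorModel, ObservationRecord, Subject

#: Population medians of the final model (Ke, V0, kcp, kpc).
MEDIAN_PARAMS = dict(ke=0.08, v0=7.20, kcp=0.28, kpc=0.34)
#: Population means/SDs of the final model.
SUMMARY = {
    "ke": (0.09, 0.04),
    "v0": (7.71, 2.70),
    "kcp": (0.44, 0.38),
    "kpc": (0.46, 0.35),
}

DAY3_TIMES = np.array([48.0, 49, 50, 51, 52, 54, 56, 60, 72])


@pytest.fixture
def median_params() -> PKParameters:
    return PKParameters(**MEDIAN_PARAMS)


@pytest.fixture
def reference_cov() -> Covariates:
    return Covariates(weight=78.0)


@pytest.fixture
def label_regimen() -> Regimen:
    """70 mg load then 50 mg daily for 3 days, 1-h infusions."""
    return Regimen.daily(70.0, 50.0, 3)


@pytest.fixture
def gamma_error() -> ErrorModel:
    return ErrorModel(c0=0.05, c1=0.08, mode="gamma", scale=0.654)


def make_subject(
    sid: str,
    params: PKParameters,
    regimen: Regimen,
    times: np.ndarray,
    em: ErrorModel,
    rng: np.random.Generator | None = None,
    weight: float = 78.0,
    noise: float = 1.0,
) -> Subject:
    """Subject with observations simulated from the model plus assay noise."""
    cov = Covariates(weight=weight)
    pred = concentration_profile(params, cov, regimen, times).concentrations
    if rng is not None and noise > 0:
        from caspopk.popfit import observation_sd

        sd = noise * np.asarray(observation_sd(em, pred))
        pred = np.maximum(pred + rng.normal(0.0, 1.0, pred.size) * sd, 0.0)
    obs = [ObservationRecord(float(t), float(c)) for t, c in zip(times, pred)]
    return Subject(id=sid, regimen=regimen, observations=obs, covariates=cov)
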