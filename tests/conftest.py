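from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from pahtk import load_params, process_voids, simulate_frame

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def design(params):
    return params[0]


@pytest.fixture(scope="session")
def analytes(params):
    return params[1]


@pytest.fixture(scope="session")
def noise_free(params):
    """Deterministic variant of the default conditions (all noise off)."""
    design, analytes = params
    d = replace(design, volume_cv=0.0, creatinine_subject_cv=0.0,
                creatinine_void_cv=0.0, baseline_subject_cv=0.0,
                ke_subject_cv=0.0, unscheduled_void_rate=0.0)
    a = {k: replace(v, assay_cv=0.0, dose_cv=0.0) for k, v in analytes.items()}
    return d, a


@pytest.fixture(scope="session")
def voids(design, analytes):
    return simulate_frame(design, analytes, seed=11)


@pytest.fixture(scope="session")
def samples(voids, analytes):
    df, _ = process_voids(voids, analytes, expected=270)
    return df
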