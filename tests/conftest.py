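import numpy as np
import pytest

from nanobmd import default_contexts, default_study_design, reference
from nanobmd.bmd import ResponseTable
from nanobmd.synth import EndpointTruth, generate_dose_response


@pytest.fixture(scope="session")
def materials():
    return reference.reference_materials()


@pytest.fixture(scope="session")
def contexts():
    return default_contexts()


@pytest.fixture(scope="session")
def design():
    return default_study_design()


@pytest.fixture()
def m2_table():
    """A clean responder: exponential truth, CED = 5, sigma = 0.25, n = 6."""
    truth = EndpointTruth.from_ced(2, 100.0, 5.0, 0.2, 0.25)
    return generate_dose_response(
        truth, [0, 1, 3, 10], 6, np.random.default_rng(101),
        material_id="SYN", context_id="submerged_plate_24h", endpoint="IL-6",
    )


@pytest.fixture()
def flat_table():
    """A true null: constant mean, lognormal noise."""
    truth = EndpointTruth(model_id=1, a=50.0, sigma=0.25)
    return generate_dose_response(
        truth, [0, 1, 3, 10], 6, np.random.default_rng(7),
        material_id="SYN", context_id="submerged_plate_24h", endpoint="IL-6",
    )


def make_table(doses, responses, **kwargs):
    meta = dict(
        material_id="SYN", context_id="submerged_plate_24h",
        endpoint="IL-1b", metric="ug_per_cm2",
    )
    meta.update(kwargs)
    return ResponseTable(doses=np.asarray(doses, float),
                         responses=np.asarray(responses, float), **meta)
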