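import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from viscoclass.cohort import CohortConfig, default_group_specs, generate_cohort
from viscoclass.rheology import IndentationProtocol


def scaled_specs(n_per_group: int):
    return tuple(
        s.__class__(**{**s.__dict__, "n": n_per_group}) for s in default_group_specs()
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy three-group cohort, 60 measurements per group."""
    cfg = CohortConfig(group_specs=scaled_specs(60), seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def truth_table():
    """Ground-truth nine-marker table of a medium cohort (no extraction)."""
    cfg = CohortConfig(group_specs=scaled_specs(400), seed=2)
    return generate_cohort(cfg).ground_truth


@pytest.fixture(scope="session")
def protocol():
    return IndentationProtocol()


@pytest.fixture(scope="session")
def healthy_params_curve():
    """Default healthy-group mean parameters and their noiseless compliance."""
    from viscoclass.rheology import ViscoParams, creep_compliance

    params = ViscoParams(100.0, 200.0, 156.1, 50.0, 0.85, 0.20)
    curve = creep_compliance(params, np.geomspace(0.02, 10.0, 60))
    return params, curve
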