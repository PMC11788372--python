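
import pandas as pd
import pytest

from tmbjoint import Cohort, ModelParams, generate_cohort, get_preset


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams(
        alpha_z=(-0.8,), alpha_m=0.4, beta_z=(1.0,), beta_m=-0.4,
        lam=1.0, sigma_b=0.5,
    )


@pytest.fixture()
def tiny_cohort() -> Cohort:
    """Three hand-entered patients with one covariate."""
    return Cohort(
        pd.DataFrame(
            {
                "response": [1, 0, 1],
                "time": [2.0, 0.5, 4.5],
                "event": [1, 1, 0],
                "tmb_obs": [1.2, -0.3, 2.5],
                "z1": [0.1, 0.9, 0.4],
            }
        )
    )


@pytest.fixture(scope="session")
def error_free_sim():
    return generate_cohort(get_preset("error_free", seed=314))


@pytest.fixture(scope="session")
def normal_error_sim():
    return generate_cohort(get_preset("tmb_normal_error", seed=628))


@pytest.fixture(scope="session")
def misclass_sim():
    return generate_cohort(get_preset("misclass_only", seed=942))
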