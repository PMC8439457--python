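import warnings

import numpy as np
import pytest

from lakemp import synthetic_data as sd
from lakemp.models import MCMCConfig, build_hurdle_data


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_landscape():
    return sd.gen_toy_landscape(13, seed=7)


@pytest.fixture(scope="session")
def survey_67():
    return sd.gen_lake_survey(sd.LakeSimConfig(n_lakes=67, seed=5))


@pytest.fixture(scope="session")
def hurdle_data_67(survey_67):
    return build_hurdle_data(survey_67)


@pytest.fixture()
def short_mcmc():
    return MCMCConfig(chains=2, warmup=400, samples=400, seed=11)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # reduced-length chains used in tests rarely meet the full ESS gate
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*failed convergence gates.*")
        yield
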