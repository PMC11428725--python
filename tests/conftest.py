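import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from extractopt import dataset, ffd_model
from extractopt.design import STUDY_FACTORS


@pytest.fixture(scope="session")
def oak_table():
    return dataset.study_table()


@pytest.fixture(scope="session")
def factors():
    return STUDY_FACTORS


@pytest.fixture(scope="session")
def dpph_fit(oak_table):
    return ffd_model.fit_response(oak_table, "dpph")


@pytest.fixture(scope="session")
def assay_fits(oak_table):
    return ffd_model.fit_all(oak_table, ["dpph", "frap", "tpc", "tfc", "ctc", "htc"])
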