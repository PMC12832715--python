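import numpy as np
import pytest

from sepsisburden.registry_io import AGE_GROUPS, PersonRecord
from sepsisburden.sepsis_codes import default_code_lists
from sepsisburden.synthetic_registry import default_truth, generate


@pytest.fixture(scope="session")
def code_lists():
    return default_code_lists()


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=20_230)


@pytest.fixture(scope="session")
def registry_dir(tmp_path_factory, truth):
    """One generated synthetic registry bundle shared across the session."""
    outdir = tmp_path_factory.mktemp("registry")
    generate(truth, outdir)
    return outdir


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(
    cause="A419",
    causes=None,
    event_kind="death",
    age_years=70.0,
    age_group="60+",
    sex="female",
    year=2023,
    region="R01",
    comuna="01101",
):
    return PersonRecord(
        event_year=year,
        sex=sex,
        age_years=age_years,
        age_group=age_group,
        region_code=region,
        comuna_code=comuna,
        causes=tuple(causes) if causes is not None else (cause,),
        event_kind=event_kind,
    )


@pytest.fixture
def record_factory():
    return make_record


def uniform_population(n_per_group=10_000, year=2023, geography="01101"):
    return {(year, geography, g): float(n_per_group) for g in AGE_GROUPS}
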