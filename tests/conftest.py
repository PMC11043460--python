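import numpy as np
import pytest

from osteotrack import (
    CERVICAL_PARAMS,
    LUMBAR_PARAMS,
    PainThreshold,
    VertebraSeries,
    VisitRecord,
)


@pytest.fixture(scope="session")
def cervical():
    return CERVICAL_PARAMS


@pytest.fixture(scope="session")
def lumbar():
    return LUMBAR_PARAMS


@pytest.fixture(scope="session")
def lumbar_threshold():
    return PainThreshold(0.15)


@pytest.fixture(scope="session")
def cervical_threshold():
    return PainThreshold(0.08)


def make_series(rows, **kw):
    """rows: iterable of (age, ori) for a single vertebra 'P1/V1'."""
    return VertebraSeries(
        [VisitRecord("P1", "V1", float(a), float(x)) for a, x in rows], **kw
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
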