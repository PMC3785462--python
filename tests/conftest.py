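import logging

import numpy as np
import pytest

from haplopower.fixtures import euro11_spectrum


@pytest.fixture(autouse=True)
def _quiet_column_warnings(caplog):
    """Keep the all-zero-column warnings from flooding test output."""
    logging.getLogger("haplopower.pvalues").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def euro11():
    """The renormalized 11-haplogroup European example spectrum."""
    logging.disable(logging.WARNING)
    try:
        spec = euro11_spectrum()
    finally:
        logging.disable(logging.NOTSET)
    return spec


@pytest.fixture()
def rng():
    return np.random.default_rng(20130927 % 2**31)
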