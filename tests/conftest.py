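import numpy as np
import pytest

from ffpeqc import load_table2


@pytest.fixture(scope="session")
def table2():
    """The packaged 67-sample archival FFPE ovarian carcinoma QC table."""
    return load_table2()


@pytest.fixture(scope="session")
def table2_by_id(table2):
    return {r.sample_id: r for r in table2}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
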