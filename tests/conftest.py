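import numpy as np
import pytest

from denovostruct.io_formats import BranchTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def branch_table():
    return BranchTable.default()


@pytest.fixture
def six_branch_table():
    return BranchTable(
        branches=[
            ("br1", 0.1),
            ("br2", 0.3),
            ("br3", 0.5),
            ("br4", 0.94),
            ("br5", 1.0),
            ("br6", 2.41),
        ]
    )
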