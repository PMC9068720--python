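import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblage.io_core import CountTable


@pytest.fixture
def four_tip_tree():
    """Balanced 4-tip tree: ((A:1,B:1):1,(C:1,D:1):1);"""
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def three_tip_tree():
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def small_table():
    """6 samples x 5 OTUs with varied counts."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 50, size=(6, 5))
    data[:, 0] += 1  # avoid zero-total samples
    return CountTable(pd.DataFrame(
        data, index=[f"S{i}" for i in range(6)],
        columns=[f"O{i}" for i in range(5)]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
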