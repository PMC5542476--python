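import numpy as np
import pandas as pd
import pytest

from bloodpanel.io import GenePanel
from bloodpanel.simulate import default_panel_names


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    vrg, brg = default_panel_names()
    return GenePanel(vrg=vrg, brg=brg)


@pytest.fixture
def tiny_expr():
    """4 genes x 5 samples, log2 scale, one missing value."""
    values = np.array(
        [
            [8.0, 9.0, 7.0, 7.5, 8.0],
            [10.0, 10.5, 11.0, 10.0, 10.2],
            [6.7, 7.0, 6.8, np.nan, 6.9],
            [12.0, 12.1, 11.9, 12.0, 12.05],
        ]
    )
    return pd.DataFrame(
        values,
        index=["GENEA", "GENEB", "GENEC", "GENED"],
        columns=[f"s{i}" for i in range(5)],
    )


@pytest.fixture
def tiny_meta():
    return pd.DataFrame(
        {
            "group": ["case", "case", "case", "control", "control"],
            "class_label": ["viral", "viral", "viral", "healthy", "healthy"],
        },
        index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"),
    )


def write_tsv(path, text):
    path.write_text(text)
    return path
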