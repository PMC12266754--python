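import numpy as np
import pandas as pd
import pytest

from irpipe.signatures import GeneSignature


@pytest.fixture
def toy_expression() -> pd.DataFrame:
    """4 genes x 4 samples with simple hand-checkable values."""
    return pd.DataFrame(
        {
            "s1": [1.0, 4.0, 2.0, 5.0],
            "s2": [2.0, 3.0, 2.0, 5.0],
            "s3": [3.0, 2.0, 2.0, 5.0],
            "s4": [4.0, 1.0, 2.0, 5.0],
        },
        index=["g1", "g2", "CONST1", "CONST2"],
    )


@pytest.fixture
def simple_signature() -> GeneSignature:
    return GeneSignature("sig", [("g1", +1), ("g2", -1)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
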