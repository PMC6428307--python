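import numpy as np
import pandas as pd
import pytest

from mixedpc.variables import MixedDataset, VariableSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def mixed_small(rng):
    """120-row dataset with one variable of each type, mutually dependent."""
    n = 120
    x = rng.standard_normal(n)
    g_codes = rng.integers(0, 3, size=n)
    y = x + 0.5 * g_codes + rng.standard_normal(n)
    o_codes = (y > np.quantile(y, [0.33, 0.66]).reshape(-1, 1)).sum(axis=0)
    glev = np.array(["a", "b", "c"], dtype=object)
    olev = np.array(["1", "2", "3"], dtype=object)
    frame = pd.DataFrame({
        "X": x, "G": glev[g_codes], "Y": y, "O": olev[o_codes],
    })
    specs = [
        VariableSpec("X", "continuous"),
        VariableSpec("G", "nominal", ("a", "b", "c")),
        VariableSpec("Y", "continuous"),
        VariableSpec("O", "ordinal", ("1", "2", "3")),
    ]
    return MixedDataset(frame, specs)
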