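import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xenomir.qpcr import CrtMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def build_matrix(array, donors=None, timepoints=("T0", "T3"), tissue="plasma",
                 features=None) -> CrtMatrix:
    """CrtMatrix from a 2-D array; columns ordered donor-major over timepoints."""
    arr = np.asarray(array, dtype=float)
    n_feat, n_samp = arr.shape
    if donors is None:
        donors = n_samp // len(timepoints)
    prefix = "P" if tissue == "plasma" else "C"
    cols = [
        f"{prefix}_{d}_{tp[1:]}" for d in range(1, donors + 1) for tp in timepoints
    ]
    assert len(cols) == n_samp
    feats = features or [f"miR-{i + 1:03d}" for i in range(n_feat)]
    return CrtMatrix(pd.DataFrame(arr, index=feats, columns=cols))


@pytest.fixture
def paired_matrix():
    """5 donors x (T0, T3), 4 features, fully observed, hand-set values."""
    rng = np.random.default_rng(42)
    base = np.array([20.0, 24.0, 28.0, 31.0])[:, None]
    vals = base + rng.normal(0, 0.3, size=(4, 10))
    return build_matrix(vals)


@pytest.fixture
def toy_catalog():
    from xenomir.xenomap import MiRNACatalog

    return MiRNACatalog.from_pairs(
        "host",
        [
            ("mir-a", "ACGTACGTACGTACGTACGT"),
            ("mir-b", "TTTTCCCCGGGGAAAATTTT"),
            ("mir-c", "ACGGACGTACGTACGTACGT"),  # 1 substitution from mir-a
        ],
    )
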