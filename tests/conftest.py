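import numpy as np
import pandas as pd
import pytest

from nichesig import BitscoreMatrix, ENVIRONMENT, GASTROINTESTINAL


@pytest.fixture
def tiny_matrix() -> BitscoreMatrix:
    """3 genes x 4 strains, one absence."""
    frame = pd.DataFrame(
        {
            "S1": [100.0, 55.0, 210.0],
            "S2": [98.0, 50.0, 205.0],
            "S3": [101.0, np.nan, 200.0],
            "S4": [99.0, 52.0, 220.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
    )
    return BitscoreMatrix(frame, provenance="fixture")


@pytest.fixture
def tiny_labels() -> pd.Series:
    return pd.Series(
        {
            "S1": ENVIRONMENT,
            "S2": ENVIRONMENT,
            "S3": GASTROINTESTINAL,
            "S4": GASTROINTESTINAL,
        },
        name="habitat",
    )
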