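import numpy as np
import pandas as pd
import pytest

from lipidyn.quantify import (
    DEFAULT_REPLICATES,
    AbundanceMatrix,
    SampleMeta,
    Units,
)


def study_design(replicates=None):
    """Sample metadata for the seven-stage lipidome design (5,5,5,4,4,3,3)."""
    replicates = replicates or DEFAULT_REPLICATES
    metas = []
    for stage, n in replicates.items():
        for r in range(1, n + 1):
            metas.append(SampleMeta(f"{stage}_r{r}", stage, r))
    return tuple(metas)


def matrix_from_values(values: np.ndarray, metas, units=Units.zscore, features=None):
    feats = features or [f"f{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=feats, columns=[m.sample_id for m in metas])
    return AbundanceMatrix(df, tuple(metas), units)


@pytest.fixture(scope="session")
def design():
    return study_design()


@pytest.fixture(scope="session")
def stage_codes(design):
    return np.array([m.stage_code for m in design], dtype=float)
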