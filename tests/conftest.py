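from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qpaintlib import (
    AcquisitionParams,
    GeneratorConfig,
    KineticsModel,
    LocalizationTable,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def kin() -> KineticsModel:
    return KineticsModel()


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


def make_table(frames, x, y, unc=None, **meta) -> LocalizationTable:
    frames = np.asarray(frames, dtype=np.int64)
    if unc is None:
        unc = np.full(len(frames), 9.0)
    df = pd.DataFrame(
        {
            "frame": frames,
            "x_nm": np.asarray(x, dtype=float),
            "y_nm": np.asarray(y, dtype=float),
            "uncertainty_nm": np.asarray(unc, dtype=float),
        }
    )
    return LocalizationTable(df=df, **meta)


@pytest.fixture()
def random_table() -> LocalizationTable:
    rng = np.random.default_rng(42)
    n = 400
    return make_table(
        rng.integers(0, 1000, n),
        rng.uniform(0, 2000, n),
        rng.uniform(0, 2000, n),
        rng.uniform(2, 20, n),
    )
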