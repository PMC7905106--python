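import numpy as np
import pandas as pd
import pytest

from manowave.design import build_design_matrices
from manowave.preprocess import PressureRecording, RecordingMeta
from manowave.wavelet import FrequencyGrid, ScaleGrid


@pytest.fixture(scope="session")
def fs():
    return 10.0


@pytest.fixture(scope="session")
def grid33():
    return FrequencyGrid.from_band(n=33)


@pytest.fixture(scope="session")
def grid9():
    return FrequencyGrid.from_band(n=9)


@pytest.fixture(scope="session")
def scales33(grid33):
    return ScaleGrid.for_grid(grid33)


@pytest.fixture
def flat_recording():
    rng = np.random.default_rng(0)
    p = np.full((4, 1200), 20.0) + rng.normal(0, 0.01, (4, 1200))
    return PressureRecording(p, fs=10.0, meta=RecordingMeta(nchan=4))


@pytest.fixture(scope="session")
def small_obs():
    """10 subjects x 2 meals, one region; balanced two-group design."""
    return pd.DataFrame([
        {"subject": f"s{i}", "group": "healthy" if i < 5 else "patient",
         "meal": m, "nchan": 24}
        for i in range(10) for m in ("preprandial", "postprandial")])


@pytest.fixture(scope="session")
def small_dm(small_obs):
    return build_design_matrices(small_obs, "group*meal + (1|subject)", "1")
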