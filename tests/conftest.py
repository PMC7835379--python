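import datetime as dt

import numpy as np
import pytest

from lakefui.colorimetry import load_lut
from lakefui.sceneio import QA, SceneStack
from lakefui.synthetic import LakeSpec, SceneSpec


@pytest.fixture(scope="session")
def lut():
    return load_lut()


@pytest.fixture
def single_lake_spec():
    """One 9x11 elliptical lake on a 100x140 grid, noise-free."""
    return SceneSpec(
        grid_shape=(100, 140),
        lakes=[LakeSpec(shape=("ellipse", (40, 60, 9, 11)), base_fui=5)],
        residual_level=0.01,
        seed=7,
    )


@pytest.fixture
def three_lake_spec():
    return SceneSpec(
        grid_shape=(120, 160),
        lakes=[
            LakeSpec(shape=("ellipse", (30, 40, 9, 11)), base_fui=4),
            LakeSpec(shape=("ellipse", (80, 30, 10, 8)), base_fui=8),
            LakeSpec(shape=("ellipse", (70, 110, 8, 12)), base_fui=11),
        ],
        residual_level=0.02,
        seed=1,
    )


def make_scene(bands, qa=None, date=dt.date(2005, 6, 10)):
    """Tiny SceneStack from plain arrays (helper, not a fixture)."""
    shape = next(iter(bands.values())).shape
    return SceneStack(
        date=date,
        bands={k: np.asarray(v, dtype=float) for k, v in bands.items()},
        qa=np.zeros(shape, dtype=np.uint16) if qa is None else qa,
    )


@pytest.fixture
def dates_2yr():
    start = dt.date(2000, 1, 1)
    return [start + dt.timedelta(days=8 * i) for i in range(92)]


def qa_flag(shape, bit, where=None):
    qa = np.zeros(shape, dtype=np.uint16)
    if where is None:
        qa[:] = bit
    else:
        qa[where] = bit
    return qa


QA_BITS = QA
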