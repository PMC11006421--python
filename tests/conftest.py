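import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_map(points, types):
    """Build a cell map table from coordinate/type lists."""
    points = np.asarray(points, float)
    return pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(len(points))],
        "x_um": points[:, 0],
        "y_um": points[:, 1],
        "type": list(types),
    })


@pytest.fixture
def toy_map():
    """Five cells: A(0,0), B(10,0), A(0,30), B(40,0), C(300,300)."""
    return make_map(
        [(0, 0), (10, 0), (0, 30), (40, 0), (300, 300)],
        ["A", "B", "A", "B", "C"],
    )


@pytest.fixture
def random_map():
    def _make(seed, n=300, field=500.0, types=("A", "B", "C")):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, field, size=(n, 2))
        t = rng.choice(types, size=n)
        return make_map(xy, t)

    return _make
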