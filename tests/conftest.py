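import numpy as np
import pandas as pd
import pytest

from hccimg import geometry as geo


@pytest.fixture(scope="session")
def ring():
    return geo.default_ring()


@pytest.fixture(scope="session")
def poses(ring):
    return dict(geo.build_multi_angle(ring))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_hits(rows):
    """Build a hit table from (time_ns, camera_id, plane, ix, iy, energy) rows."""
    df = pd.DataFrame(
        rows, columns=["time_ns", "camera_id", "plane", "ix", "iy", "energy_kev"]
    )
    df["angle_id"] = 0
    return df
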