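import numpy as np
import pandas as pd
import pytest

from cryopalm.calibration import ZCalibration


@pytest.fixture(scope="session")
def cal() -> ZCalibration:
    return ZCalibration.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_table(x, y, z=None, photons=1000.0, precision=10.0) -> pd.DataFrame:
    """Small localization-table helper used across test modules."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = len(x)
    df = pd.DataFrame({
        "frame": np.zeros(n, dtype=int),
        "x_nm": x,
        "y_nm": np.broadcast_to(np.asarray(y, dtype=float), (n,)).copy(),
        "photons": np.broadcast_to(np.asarray(photons, dtype=float), (n,)).copy(),
        "bg_photons": np.full(n, 10.0),
        "wx_nm": np.full(n, 160.0),
        "wy_nm": np.full(n, 160.0),
        "precision_nm": np.broadcast_to(np.asarray(precision, dtype=float), (n,)).copy(),
    })
    if z is not None:
        df["z_nm"] = np.broadcast_to(np.asarray(z, dtype=float), (n,)).copy()
    return df
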