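import numpy as np
import pytest

from startlekit import AccelRecord, HydrophoneCal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cal():
    """Monitoring-hydrophone calibration at the four test frequencies."""
    return HydrophoneCal(
        sensitivity_db={1.0: -211.63, 10.0: -211.55, 25.0: -211.0, 32.0: -211.3},
        gain_db=0.0,
        fs=96_000.0,
    )


def make_record(xyz: np.ndarray, fs: float = 320.0, **kw) -> AccelRecord:
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return AccelRecord(fs=fs, ax=xyz[:, 0], ay=xyz[:, 1], az=xyz[:, 2], **kw)


@pytest.fixture
def make_rec():
    return make_record
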