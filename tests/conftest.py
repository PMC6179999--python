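import numpy as np
import pytest

from wntflux.models import DetectionVolume


@pytest.fixture(scope="session")
def volume() -> DetectionVolume:
    """Default confocal calibration: w0 = 0.2 um, structure parameter 5."""
    return DetectionVolume(w0=0.2, z0=1.0)


@pytest.fixture(scope="session")
def lag_grid() -> np.ndarray:
    return np.geomspace(2e-6, 10.0, 160)
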