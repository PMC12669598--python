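import numpy as np
import pytest

from scintidose.calibration import auto_calibrate
from scintidose.physics_tables import DetectorGeometry, load_default_tables
from scintidose.pulse_simulator import (DetectorConfig, SourceModel,
                                        detect_and_digitize)


@pytest.fixture(scope="session")
def tables():
    return load_default_tables()


@pytest.fixture(scope="session")
def attenuation(tables):
    return tables[0]


@pytest.fixture(scope="session")
def dose_table(tables):
    return tables[1]


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def am241_stream(config, attenuation):
    """A bright seeded Am-241 acquisition shared across calibration tests."""
    src = SourceModel(kind="am241", intensity=2000.0)
    rng = np.random.default_rng(42)
    energies = src.sample(200_000, rng)
    return detect_and_digitize(energies, src.intensity, config, 100.0, rng,
                               attenuation=attenuation)


@pytest.fixture(scope="session")
def am241_calibration(am241_stream, config):
    cal, hist = auto_calibrate(am241_stream, config)
    return cal
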