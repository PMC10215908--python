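import numpy as np
import pytest

import fluoarea as fa


@pytest.fixture
def rng():
    return np.random.default_rng(20230530)


@pytest.fixture(scope="session")
def table1_path():
    return fa.fixture_path("table1.csv")


@pytest.fixture(scope="session")
def table2_path():
    return fa.fixture_path("table2.csv")


@pytest.fixture(scope="session")
def table1():
    return fa.load_calibration_table(fa.fixture_path("table1.csv"))


@pytest.fixture(scope="session")
def table1_calibration():
    table = fa.load_calibration_table(fa.fixture_path("table1.csv"))
    return fa.fit_calibration_set(table)


@pytest.fixture(scope="session")
def printed_curves():
    """Calibration curves built from the coefficients as printed, not refitted."""
    return fa.CalibrationSet(curves=(
        fa.DistanceCurve(distance=50.0, a0=-18.7376, a1=0.0285, r2=0.9951, n=8),
        fa.DistanceCurve(distance=75.0, a0=18.6109, a1=0.0725, r2=0.9981, n=8),
        fa.DistanceCurve(distance=100.0, a0=-18.1121, a1=0.136, r2=0.9968, n=8),
    ))
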