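import pytest
from hypothesis import settings

from tubeqc.calibration import CalibrationPoint, fit_calibration

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def six_point_design():
    """Default six working calibration levels with near-proportional
    absorbances (slightly noisy, so dispersion statistics are non-zero)."""
    return [
        CalibrationPoint(0.25, 0.051),
        CalibrationPoint(0.5, 0.102),
        CalibrationPoint(1.0, 0.204),
        CalibrationPoint(2.0, 0.406),
        CalibrationPoint(3.0, 0.612),
        CalibrationPoint(4.0, 0.810),
    ]


@pytest.fixture(scope="session")
def six_point_fit(six_point_design):
    return fit_calibration(six_point_design)
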