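import numpy as np
import pytest

from vpcharts import ChartConfig, load_scenario
from vpcharts.calibration import CalibrationSettings, calibrate_ucl, \
    calibrate_vp_limits


@pytest.fixture(scope="session")
def p2():
    """Two-profile benchmark scenario (p=2, q=2)."""
    return load_scenario("paper_p2")


@pytest.fixture(scope="session")
def cfg():
    return ChartConfig()


@pytest.fixture(scope="session")
def mewma_fp_ucl(p2):
    """FP Max-MEWMA control limit calibrated at alpha=0.005, n=4.

    Shared across the table-reproduction and property tests; calibrated
    once at 10000 replications with a 1% ARL tolerance.
    """
    settings = CalibrationSettings(reps=10000, seed=101, tol=0.01)
    res = calibrate_ucl("max_mewma", p2.model, p2.chart_config,
                        alpha=0.005, n=4, settings=settings)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def mewma_vp_design(p2):
    """Fully calibrated VP design (UCL1/2, UWL1/2) for the Max-MEWMA chart."""
    settings = CalibrationSettings(reps=10000, seed=202, tol=0.01)
    design, diag = calibrate_vp_limits(
        "max_mewma", p2.model, p2.vp_design, p2.chart_config, settings=settings
    )
    assert diag["ucl1"].converged and diag["ucl2"].converged
    return design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
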