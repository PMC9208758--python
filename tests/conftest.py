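import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from munit_task.core import DriveTrace, ForceTrace
from munit_task.engine import BufferConfig, standard_targets
from munit_task.synth import MotorUnitParams


@pytest.fixture
def cfg():
    return BufferConfig()


@pytest.fixture
def geoms():
    return standard_targets()


@pytest.fixture
def reversed_pair():
    """MU pair with reversed de-recruitment order: MU1 de-recruits at a
    higher force (2.5) than MU2 (1.5), enabling the three-stage strategy."""
    mu1 = MotorUnitParams("mu1", theta_on=3.0, theta_off=2.5, r_min=8.0,
                          rate_gain=0.45, r_sat=12.0, isi_cov=0.1)
    mu2 = MotorUnitParams("mu2", theta_on=4.0, theta_off=1.5, r_min=8.5,
                          rate_gain=0.5, r_sat=12.5, isi_cov=0.1)
    return mu1, mu2


def constant_drive(level: float, duration: float, fs: float = 512.0) -> DriveTrace:
    return DriveTrace(fs=fs, values=np.full(int(round(duration * fs)), level))


def linear_force(duration: float, slope: float = 1.0,
                 fs: float = 512.0) -> ForceTrace:
    n = int(round(duration * fs))
    return ForceTrace(fs=fs, values=slope * np.arange(n) / fs)


def make_unit(theta_on, theta_off=None, r_min=8.0, rate_gain=0.5, r_sat=14.0,
              isi_cov=0.0, unit_id="u"):
    return MotorUnitParams(unit_id, theta_on=theta_on,
                           theta_off=theta_on if theta_off is None else theta_off,
                           r_min=r_min, rate_gain=rate_gain, r_sat=r_sat,
                           isi_cov=isi_cov)
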