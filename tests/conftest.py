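import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mbwqc.breaths import BreathTable
from mbwqc.simulator import SimConfig, simulate_trial

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_table(v_exp, c_et=None, c_insp=None, duration=1.5, sample_rate=200.0):
    """Synthetic BreathTable with consistent half-sine geometry."""
    v_exp = np.asarray(v_exp, dtype=float)
    n = len(v_exp)
    per = int(round(duration * sample_rate))
    insp_start = np.arange(n) * per
    return BreathTable(
        insp_start=insp_start,
        exp_start=insp_start + per // 2,
        exp_end=insp_start + per,
        v_insp=v_exp.copy(),
        v_exp=v_exp,
        duration=np.full(n, duration),
        peak_flow=v_exp * np.pi / duration,
        c_et=c_et,
        c_insp_mean=c_insp,
    )


@pytest.fixture(scope="session")
def clean_trial():
    """One clean noise-free spiroware-like trial with ground truth."""
    return simulate_trial(SimConfig(seed=3))


@pytest.fixture()
def clean_cfg():
    return SimConfig(seed=3)
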