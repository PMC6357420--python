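import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import amap

# study conditions for end-to-end runs: 20 s of 1 s strides at 500 Hz keeps
# the exact k-means fast while leaving ~18 analyzable strides
TRIAL_DURATION_S = 20.0
TRIAL_RATE_HZ = 500.0
RECOVERY_NOISE_SD = 0.05


@pytest.fixture(scope="session")
def healthy_run():
    """Healthy simulated trial plus its full pipeline analysis."""
    model = amap.healthy_model(noise_sd=RECOVERY_NOISE_SD, seed=3)
    emg, grf, truth = amap.simulate_trial(
        model, duration_s=TRIAL_DURATION_S, rate_hz=TRIAL_RATE_HZ
    )
    analysis = amap.analyze_trial(emg, grf, paretic_leg="left")
    return model, emg, grf, truth, analysis


@pytest.fixture(scope="session")
def hemiparetic_run():
    """Hemiparetic simulated trial plus its full pipeline analysis."""
    model = amap.hemiparetic_model(noise_sd=RECOVERY_NOISE_SD, seed=4)
    emg, grf, truth = amap.simulate_trial(
        model, duration_s=TRIAL_DURATION_S, rate_hz=TRIAL_RATE_HZ
    )
    analysis = amap.analyze_trial(emg, grf, paretic_leg="left")
    return model, emg, grf, truth, analysis


@pytest.fixture(scope="session")
def component_cohort():
    """Healthy component-space cohort: 20 subjects, both legs."""
    return amap.sample_component_cohort(20, seed=11, legs=2)


@pytest.fixture
def symmetric_events():
    """Ten symmetric 1 s strides: stance 60%, contralateral lag 50%."""
    hs_l = np.arange(0.0, 10.0, 1.0)
    to_l = hs_l + 0.6
    hs_r = hs_l + 0.5
    to_r = hs_r - 0.4  # contralateral TO at 0.1, 1.1, ... (leading TO)
    return amap.GaitEvents(
        heel_strikes={"left": hs_l, "right": hs_r},
        toe_offs={"left": to_l, "right": to_r},
    )
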