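import numpy as np
import pytest

from edasites.decompose import build_response_kernel
from edasites.io import PipelineConfig
from edasites.simulate import SimulationConfig, SiteProfile


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def kernel_8hz():
    return build_response_kernel(0.7, 2.0, 8.0)


@pytest.fixture(scope="session")
def quiet_sim_config():
    """Deterministic two-site config with every stochastic term switched off."""
    sites = [
        SiteProfile("finger", tonic_level_us=6.0, tonic_drift_sd=0.0,
                    responsiveness=0.0, walking_noise_sd=0.0,
                    lift_artifact_rate=0.0, lift_artifact_amp_us=0.0),
        SiteProfile("foot", tonic_level_us=5.0, tonic_drift_sd=0.0,
                    responsiveness=0.0, walking_noise_sd=0.0,
                    lift_artifact_rate=0.0, lift_artifact_amp_us=0.0),
    ]
    return SimulationConfig(
        n_subjects=1,
        site_profiles=sites,
        measurement_noise_sd_us=0.0,
        seed=7,
    )


def make_bump_train(times_s, amps, fs, duration_s, kernel):
    """Phasic trace with unit-peak kernel bumps at given times/amplitudes."""
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    for t, a in zip(times_s, amps):
        i = int(round(t * fs))
        seg = kernel[: n - i]
        x[i : i + seg.size] += a * seg
    return x
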