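import pytest

from rhizotrace import ScenarioConfig, generate

MERGE_KEY = ["plot_id", "species", "n_rate", "depth_top_cm", "depth_bottom_cm"]


@pytest.fixture(scope="session")
def noise_free_sim():
    """One simulated experiment with all measurement noise switched off."""
    cfg = ScenarioConfig(seed=11, noise_cv=0.0, delta_noise_sd_permil=0.0)
    return generate(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """One simulated experiment under the study's default noise levels."""
    cfg = ScenarioConfig(seed=5)
    return generate(cfg)
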