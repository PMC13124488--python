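import numpy as np
import pytest
from hypothesis import settings

import isletca as ic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_sim():
    """One 'clean' synthetic islet (50 cells, planted subpopulations)."""
    params = ic.preset("clean", rng_seed=1)
    traces, centroids, timeline, truth = ic.simulate_islet(params)
    return params, traces, centroids, timeline, truth


@pytest.fixture(scope="session")
def clean_result(clean_sim):
    """Full pipeline result on the clean islet (reduced shuffle count)."""
    _, traces, centroids, timeline, _ = clean_sim
    cfg = ic.RunConfig(n_shuffles=500, rng_seed=1)
    return ic.run_full_analysis(
        cfg, traces=traces, centroids=centroids, timeline=timeline
    )


def markov_burst(n_frames: int, rng: np.random.Generator,
                 p_switch: float = 0.05) -> np.ndarray:
    """Stationary two-state activity chain (mean burst/gap ~20 frames)."""
    flips = rng.random(n_frames) < p_switch
    return (np.cumsum(flips) % 2).astype(np.uint8)
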