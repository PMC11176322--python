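import numpy as np
import pytest

from scnakit.synthetic import SimConfig, generate_clone_pair, sample_events


@pytest.fixture(scope="session")
def small_clone_pair():
    """A modest clone pair with planted events, reused across caller tests."""
    cfg = SimConfig(seed=42, n_bins=1500, n_chromosomes=10)
    rng = np.random.default_rng(7)
    events = sample_events(rng, cfg, 8)
    prog, daughter, snps, truth = generate_clone_pair(
        cfg, ploidy=3, events=events, mean_depth=200.0
    )
    return cfg, prog, daughter, snps, truth
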