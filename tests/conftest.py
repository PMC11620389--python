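import numpy as np
import pytest

from lexepi.synthetic_data import GeneratorConfig, generate_lexicon, make_worked_example


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def small_lexicon():
    """60-item default-noise lexicon shared by pipeline-level tests."""
    return generate_lexicon(GeneratorConfig(n_items=60, seed=3))


@pytest.fixture(scope="session")
def noise_free_r0_6():
    """Noise-free lexicon where every item has true R0 = 6, growing items
    saturated well before the survey date."""
    cfg = GeneratorConfig(
        n_items=6,
        frac_growing=0.5,
        seed=1,
        r0_sampler=lambda rng, n: np.full(n, 6.0),
        midpoint_range=(1880.0, 1910.0),
    ).noise_free()
    return generate_lexicon(cfg)
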