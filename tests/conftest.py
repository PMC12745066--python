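import numpy as np
import pytest

from paleogm import (
    make_group_means,
    simulate_shapes,
)
from paleogm.simulate import (
    outline_bulge_effect,
    outline_template_coords,
    talus_bulge_effect,
    talus_template,
    talus_template_coords,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_250_927)


@pytest.fixture(scope="session")
def outline_means():
    """Two-group 2D outline means: a bulged disto-lingual quadrant vs. the
    neutral superellipse, separation 6x the default noise sd."""
    return make_group_means(
        outline_template_coords(),
        {"NEA": outline_bulge_effect(), "HS": np.zeros((24, 2))},
        effect_scale=0.06,
    )


@pytest.fixture(scope="session")
def outline_sample(outline_means):
    """30 specimens per group, noise sd 0.01, with geography metadata."""
    return simulate_shapes(
        outline_means, 30, noise_sd=0.01, seed=1234,
        geography={"NEA": (45.0, 5.0), "HS": (40.0, 15.0)},
    )


@pytest.fixture(scope="session")
def talus_fixture():
    """Small 3D sample on the talus-like block template (with sliding
    semilandmark roles)."""
    template = talus_template()
    means = make_group_means(
        talus_template_coords(),
        {"NEA": talus_bulge_effect(), "HS": np.zeros((30, 3))},
        effect_scale=0.06,
    )
    configs = simulate_shapes(means, 10, noise_sd=0.01, seed=99)
    return template, means, configs
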