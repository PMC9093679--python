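import numpy as np
import pytest

from botclass.simulate import SimulationDesign, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small contaminated dataset with ground truth (N=150, 3 factors)."""
    design = SimulationDesign(n_persons=150, n_factors=3, prop_bots=0.25, seed=11)
    return generate_dataset(design)


@pytest.fixture(scope="session")
def clean_dataset():
    """Humans only, fixed communality/correlation, large enough for recovery."""
    design = SimulationDesign(
        n_persons=2000, n_factors=2, prop_bots=0.0,
        communality_mean_range=(0.5, 0.5), communality_halfwidth=0.0,
        rho_range=(0.3, 0.3), seed=7)
    return generate_dataset(design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
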