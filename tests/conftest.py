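import numpy as np
import pytest

from movemetric import SimConfig, make_dataset


def small_config(seed: int = 0, **kw) -> SimConfig:
    """Scaled-down study: 4 learners, short template, 24 rated pairs."""
    defaults = dict(
        n_participants=4, n_sessions=3, trials_per_session=3,
        template_length=240, n_pairs=24, seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic dataset (feature-basis ratings)."""
    ds, truth = make_dataset(small_config(seed=7))
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
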