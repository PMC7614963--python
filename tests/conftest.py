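import numpy as np
import pytest

import selfrecon as sr


@pytest.fixture(scope="session")
def column_dist():
    """Acquisition density: 64-wide column sampling at R = 4."""
    return sr.build_column_density(64, 4.0, order=8, center_cols=10, height=64)


@pytest.fixture(scope="session")
def lambda_dist():
    """Partition density: column sampling at R = 2, capped below 1."""
    return sr.build_column_density(
        64, 2.0, order=8, center_cols=10, cap_epsilon=1e-3, height=64
    )


@pytest.fixture(scope="session")
def small_dataset(column_dist):
    """Six 64x64 slices, 2 coils, frozen acquisition masks."""
    return sr.make_dataset(2, 3, column_dist, rng_seed=7, n_coils=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_spec_uniform():
    """Two locations, deterministic unit data, i.i.d. half-probability masks."""
    return sr.DiscreteToySpec(n=2, alphabet=[1.0], p=[0.5, 0.5], p_tilde=[0.5, 0.5])


def random_kspace(rng, n_coils=2, height=8, width=8):
    return rng.standard_normal((n_coils, height, width)) + 1j * rng.standard_normal(
        (n_coils, height, width)
    )
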