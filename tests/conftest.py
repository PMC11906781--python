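import numpy as np
import pytest

import chemometab as cm


def simulate_prepped(seed: int, effect_size: float, n_bio: int, **kwargs):
    """Generate -> normalize -> drop QCs -> average replicates; returns (X, y)."""
    cfg = cm.SimulationConfig(
        seed=seed, effect_size=effect_size, n_bio_per_class=n_bio, **kwargs
    )
    table, _ = cm.generate_dataset(cfg)
    pre, _ = cm.preprocess_table(table)
    rec = pre.subset_samples(~pre.sample_meta["qc"].astype(bool).to_numpy())
    avg = cm.average_replicates(rec)
    return (
        avg.intensities.to_numpy(dtype=float),
        avg.sample_meta["class"].to_numpy(),
    )


@pytest.fixture(scope="session")
def separable_data():
    """Strongly class-separated 4-group dataset, 10 biological reps per class."""
    return simulate_prepped(seed=1, effect_size=2.0, n_bio=10)


@pytest.fixture(scope="session")
def null_data():
    """Large balanced dataset with labels permuted: no real class signal."""
    from chemometab.core import rng_for

    X, y = simulate_prepped(seed=1, effect_size=2.0, n_bio=20)
    y_perm = rng_for(1, "null-permutation").permutation(y)
    return X, y_perm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
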