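import numpy as np
import pytest

from pathomil import synthetic
from pathomil.features import FeatureBag


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients, small bags: fast fixture for plumbing-level tests."""
    spec = synthetic.BagSpec(
        n_patients=60,
        tiles_per_patient_range=(10, 20),
        feature_dim=8,
        witness_rate=0.3,
        effect_size=3.0,
        prevalence=0.5,
        seed=11,
    )
    return synthetic.generate_feature_bags(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_bag(rng, n_tiles, d, pid="P0") -> FeatureBag:
    return FeatureBag(
        patient_id=pid,
        slide_ids=(f"{pid}_s0",),
        features=rng.standard_normal((n_tiles, d)),
        tile_coords=[(f"{pid}_s0", i, 0) for i in range(n_tiles)],
        labels={"ER": int(rng.random() < 0.5)},
    )
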