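import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vimstab.forest_vim import Dataset, ForestConfig, fit_forest
from vimstab.synthetic import SynthSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """n=120, d=8, 3 classes, 3 informative + 1 redundant + noise."""
    return generate(
        SynthSpec(
            n_sample=120,
            n_feature=8,
            n_class=3,
            n_informative=3,
            class_separation=3.5,
            correlated_blocks=1,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_forest(small_dataset):
    return fit_forest(small_dataset, ForestConfig(ntree=80, mtry=3, seed=5))


@pytest.fixture(scope="session")
def single_signal_dataset():
    """One informative feature among noise, two classes."""
    return generate(
        SynthSpec(
            n_sample=100,
            n_feature=6,
            n_class=2,
            n_informative=1,
            class_separation=4.0,
            seed=23,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_scores(values, method="MDG", seed=0):
    """ImportanceScores over feature ids 1..len(values)."""
    from vimstab.forest_vim import ImportanceScores

    values = np.asarray(values, dtype=float)
    return ImportanceScores(
        method=method,
        feature_ids=np.arange(1, len(values) + 1),
        values=values,
        seed=seed,
    )


def ranking_from_order(order):
    """FeatureRanking with the given explicit feature-id order."""
    from vimstab.forest_vim import FeatureRanking

    order = np.asarray(order, dtype=int)
    return FeatureRanking(
        order=order, position={int(f): r + 1 for r, f in enumerate(order)}
    )
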