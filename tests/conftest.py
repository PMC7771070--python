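import numpy as np
import pytest

import hgtsite as h


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal benchmark: references, truth sites, windows."""
    cfg = h.SimulationConfig(
        n_refs=2, ref_length=40_000, sites_per_ref=30, arm_length_range=(8, 8),
        corruption=0.05, seed=42,
    )
    sample_set, refs, sites = h.simulate_labeled_set(cfg, 60, 60)
    return cfg, sample_set, refs, sites


def _tiny_spec():
    return h.ModelSpec(n_res_blocks=2, filters=16, dense_units=32, dropout_rates=(0.1, 0.25))


@pytest.fixture()
def tiny_spec():
    return _tiny_spec()


@pytest.fixture(scope="session")
def trained_small_model():
    """A compact classifier trained on a planted-signal set.

    16 filters and 2 residual blocks learn the planted inverted-repeat
    signature quickly; used by tests that need a model with real signal.
    """
    cfg = h.SimulationConfig(
        n_refs=4, ref_length=40_000, sites_per_ref=125, site_spacing=150,
        arm_length_range=(8, 8), corruption=0.05, seed=7,
    )
    sample_set, refs, sites = h.simulate_labeled_set(cfg, 500, 500)
    sample_set = h.split_dataset(sample_set, (0.7, 0.0, 0.3), seed=7)
    train_set, test_set = sample_set.subset("train"), sample_set.subset("test")
    model = h.build_model(_tiny_spec(), seed=7)
    h.train(model, train_set, None, h.TrainConfig(epochs=25, learning_rate=0.01, seed=7))
    return model, train_set, test_set, refs, sites


class StubModel:
    """Duck-typed constant-output model for geometry tests."""

    def __init__(self, value: float, input_length: int = 100):
        self.value = value
        self.spec = h.ModelSpec(input_length=input_length)
        self.n_rows_seen = []

    def predict_proba(self, x, batch_size=256, stem_mask=None):
        self.n_rows_seen.append(x.shape[0])
        return np.full(x.shape[0], self.value, dtype=np.float64)


@pytest.fixture()
def stub_model_factory():
    return StubModel
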