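"""Shared fixtures: the standard 2-class embedded-motif dataset and a
model trained on it once per session.

The fixture conditions are the desk-scale study conditions used
throughout: 1500 sequences per class plus 750 unlabeled negatives,
100 nt windows, one 8-mer motif per class embedded in 90% of that
class's sequences at center +/- 20 nt, instances sampled from a sharp
PWM. The model is a 2-member ensemble with a motif-initialized
32 x 12 first layer, trained for at most 5 epochs.
"""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import motifeffect as me

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from motifeffect.motifs import consensus
from motifeffect.synthetic import decoy_panel, demo_spec, pwm_from_consensus

FIXTURE_SEED = 11

#: small ensemble used by every training test
SMALL_MODEL = dict(
    ensemble_size=2,
    first_layer=(32, 12),
    member_second_layers=[(8, 5), (16, 9)],
    epochs=5,
    batch_size=32,
    learning_rate=2e-3,
)


def small_config(seed: int, **overrides) -> me.ModelConfig:
    kw = {**SMALL_MODEL, **overrides}
    return me.ModelConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def pwm_pair():
    return pwm_from_consensus("motifA", "TGACTCAG"), pwm_from_consensus("motifB", "CACGTGAC")


@pytest.fixture(scope="session")
def fixture_spec():
    return demo_spec(n_per_class=1500, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_data(fixture_spec):
    dataset, truth = me.generate_dataset(fixture_spec)
    return dataset, truth


@pytest.fixture(scope="session")
def fixture_split(fixture_data):
    dataset, _ = fixture_data
    return me.split_by_chromosome(dataset, ["chr18"], ["chr19"])


@pytest.fixture(scope="session")
def fixture_results(fixture_split, pwm_pair):
    """A trained model on the standard fixture (shared across tests)."""
    model = me.SequenceActivityModel(
        fixture_split, config=small_config(FIXTURE_SEED), motif_db=list(pwm_pair)
    )
    return model.fit()


@pytest.fixture(scope="session")
def fixture_backgrounds(fixture_spec):
    return me.generate_background_pool(fixture_spec, M=24, seed=FIXTURE_SEED + 1000)


@pytest.fixture(scope="session")
def fixture_panel(pwm_pair):
    """22-entry screen panel: both embedded motifs + 20 dissimilar decoys."""
    return list(pwm_pair) + decoy_panel(list(pwm_pair), seed=FIXTURE_SEED + 1000)


@pytest.fixture(scope="session")
def fixture_patterns(fixture_panel):
    return [consensus(p) for p in fixture_panel]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
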