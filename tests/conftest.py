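"""Shared fixtures: synthetic genomes and a trained model.

The expensive pieces (simulation, forest training, genome-wide
prediction) are session-scoped so the whole suite trains once and
predicts once per sample.
"""

import numpy as np
import pytest

import enhancerkit as ek
from enhancerkit import classifier, signal, synthetic, training
from enhancerkit.signal import input_normalize_marks


@pytest.fixture(scope="session")
def small_bins():
    return ek.GenomeBins({"chr1": 1000, "chr2": 500}, bin_size=100)


@pytest.fixture(scope="session")
def sim_train():
    cfg = ek.SimConfig(seed=11)
    return synthetic.simulate_expression(synthetic.simulate_tracks(cfg))


@pytest.fixture(scope="session")
def sim_test():
    cfg = ek.SimConfig(seed=21)
    return synthetic.simulate_expression(synthetic.simulate_tracks(cfg))


@pytest.fixture(scope="session")
def training_sets(sim_train):
    pool = synthetic.training_pool_from_truth(sim_train, seed=11)
    set1 = training.assemble_training_set(pool, "classifier1", seed=1)
    set2 = training.assemble_training_set(pool, "classifier2", seed=2)
    return pool, set1, set2


@pytest.fixture(scope="session")
def train_marks(sim_train):
    s = sim_train.cfg.samples[0]
    return input_normalize_marks(sim_train.raw_tracks[s], sim_train.input_tracks[s])


@pytest.fixture(scope="session")
def model(training_sets, train_marks):
    _, set1, set2 = training_sets
    return classifier.train(set1, set2, train_marks, seed=3)


@pytest.fixture(scope="session")
def predictions(model, sim_test):
    """Genome-wide probability tracks for every sample of the test genome."""
    return {
        s: classifier.predict(
            model,
            input_normalize_marks(sim_test.raw_tracks[s], sim_test.input_tracks[s]),
        )
        for s in sim_test.cfg.samples
    }


def make_probability_track(bins, p_enhancer):
    """ProbabilityTrack with p_active = 1 so p_enhancer carries the values."""
    ones = {c: np.ones(bins.n_bins(c)) for c in bins.chroms}
    return classifier.ProbabilityTrack(bins, ones, dict(p_enhancer), dict(p_enhancer))
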