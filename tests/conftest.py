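import numpy as np
import pytest

import lintracer as lt


@pytest.fixture
def ground_truth_8():
    return lt.parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")


@pytest.fixture(scope="session")
def shallow_colonies():
    """Three-state-style simulated colonies (|S|=2, L=10, mu=0.15), 200 of
    them: the shared training corpus for classifier tests."""
    cfg = lt.SimConfig(
        n_units=10,
        depth_choices=(2, 3, 4, 5, 6),
        mu_choices=(0.15,),
        alphabet=lt.Alphabet.mouse_style(),
        n_colonies=200,
    )
    return lt.sample_experiment(cfg, np.random.default_rng(42))


@pytest.fixture(scope="session")
def level1_model(shallow_colonies):
    """Level-1 classifier trained on the first 150 shared colonies."""
    table = lt.build_training_table(shallow_colonies[:150], [1])
    return lt.train_level_model(table, level=1, seed=7)


@pytest.fixture(scope="session")
def small_models(shallow_colonies):
    """Level 1-3 models on a small corpus, for reconstruction contracts."""
    table = lt.build_training_table(shallow_colonies[:60], [1, 2, 3])
    return {
        t: lt.train_level_model(table, level=t, seed=t) for t in (1, 2, 3)
    }
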