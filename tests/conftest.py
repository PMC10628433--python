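import pytest

from sbmlannot import synthgen
from sbmlannot.predict import PredictionParams


@pytest.fixture(scope="session")
def fixture_db_model():
    return synthgen.paper_fixture()


@pytest.fixture(scope="session")
def fixture_db(fixture_db_model):
    return fixture_db_model[0]


@pytest.fixture(scope="session")
def fixture_model(fixture_db_model):
    return fixture_db_model[1]


@pytest.fixture(scope="session")
def default_params():
    return PredictionParams()


@pytest.fixture(scope="session")
def synth_corpus():
    """Clean synthetic corpus: 50 terms, 20 reactions, no noise/dropout."""
    cfg = synthgen.SynthConfig(n_species_terms=50, n_reactions=20,
                               name_noise_rate=0.0, participant_dropout_rate=0.0,
                               seed=11)
    db = synthgen.generate_reference_db(cfg)
    model, truth = synthgen.generate_model(db, cfg)
    return db, model, truth
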