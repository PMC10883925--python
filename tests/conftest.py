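import numpy as np
import pytest

from nadescreen import chemtext, corpus, model, syndata

WORLD_SEED = 7


@pytest.fixture(scope="session")
def world():
    return syndata.make_world(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def small_db(world):
    return syndata.make_labeled_db(world, n=300, n_stable=240, seed=WORLD_SEED)


@pytest.fixture(scope="session")
def small_corpus(world):
    return syndata.make_reaction_corpus(world, 200, seed=WORLD_SEED)


@pytest.fixture(scope="session")
def vocab(small_corpus):
    return chemtext.build_vocabulary(small_corpus, 30000)


@pytest.fixture(scope="session")
def tiny_config():
    return model.ElectraConfig.desk_scale(
        hidden_size=32, num_heads=2, ffn_size=64, pretrain_epochs=3)


@pytest.fixture(scope="session")
def tiny_pretrained(small_corpus, vocab, tiny_config):
    pretrained, _ = model.pretrain(small_corpus, vocab, tiny_config, seed=WORLD_SEED)
    return pretrained


@pytest.fixture(scope="session")
def tiny_classifier(tiny_pretrained, small_db):
    split = corpus.split_dataset(small_db, 0.2, WORLD_SEED)
    cfg = model.FinetuneConfig(epochs=3, seed=WORLD_SEED)
    clf, _ = model.finetune_classifier(tiny_pretrained, split.train, split.test, cfg)
    return clf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
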