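import pytest

from sidfuse.corpus import Corpus, Post
from sidfuse.experiments import StudyScale, build_feature_blocks
from sidfuse.synthetic import GeneratorConfig, generate_corpus, make_fixture_lexicons


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=5).scaled(40, 360)


@pytest.fixture(scope="session")
def lexicons(small_config):
    return make_fixture_lexicons(small_config)


@pytest.fixture(scope="session")
def small_corpus(small_config, lexicons):
    return generate_corpus(small_config, lexicons)


@pytest.fixture(scope="session")
def small_blocks(small_corpus, lexicons):
    scale = StudyScale(embedding_dim=16, embedding_epochs=2, k_clusters=6, m_per_cluster=8)
    return build_feature_blocks(small_corpus, lexicons, seed=5, scale=scale)


@pytest.fixture
def hand_corpus():
    """Tiny handcrafted corpus for exact feature arithmetic."""
    return Corpus(
        [
            Post(
                id="a",
                tokens=["affect_w00", "affect_w01", "negw00", "negw01", "negw02",
                        "level1_adv0", "risk01_w00", "fill00", "fill01", "fill02"],
                pos_tags=["n", "n", "n", "n", "n", "d", "n", "u", "u", "u"],
                hour=0, minute=0,
                emojis=["Knife", "Knife", "Smile"],
                label=1,
            ),
            Post(
                id="b",
                tokens=["fill00", "fill01", "fill02", "fill03", "fill04"],
                pos_tags=["u"] * 5,
                hour=23, minute=59,
                emojis=[],
                label=0,
            ),
        ]
    )
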