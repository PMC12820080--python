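import numpy as np
import pytest

from semharm.embedding import MockEmbeddingBackend
from semharm.item_bank import ItemBank, ScaleItem, preprocess_bank
from semharm.synthetic import GeneratorConfig, generate_item_bank


@pytest.fixture
def tiny_bank() -> ItemBank:
    """Two scales, four items, hand-written descriptions."""
    return ItemBank(
        (
            ScaleItem("TLC", "1", "Poverty of speech", "restriction in the amount of spontaneous speech"),
            ScaleItem("TLC", "2", "Derailment", "ideas slip off track onto an oblique topic"),
            ScaleItem("CLANG", "1", "Excess phonetic association", "sound of a word governs the choice of the next word"),
            ScaleItem("CLANG", "2", "Poverty of speech", "markedly reduced quantity of produced speech"),
        )
    )


@pytest.fixture
def mock_backend() -> MockEmbeddingBackend:
    return MockEmbeddingBackend(seed=42, dimension=64)


@pytest.fixture
def themed_pipeline():
    """Default synthetic bank, preprocessed, with truth and a mock backend."""
    cfg = GeneratorConfig(seed=7)
    bank, truth = generate_item_bank(cfg)
    bank = preprocess_bank(bank)
    backend = MockEmbeddingBackend(seed=7, dimension=256)
    return cfg, bank, truth, backend


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
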