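"""Shared fixtures: small deterministic corpora and tiny models."""

import numpy as np
import pytest

from smilesclm import (ClmConfig, FixtureSpec, TokenVocabulary, TransformerLM,
                       build_vocabulary, generate_fixture_corpus)


@pytest.fixture(scope="session")
def small_corpus() -> list[str]:
    """100 valid, canonically unique SMILES over C/N/O."""
    return generate_fixture_corpus(FixtureSpec(n_molecules=100, seed=7))


@pytest.fixture(scope="session")
def ring_corpus() -> list[str]:
    """60 molecules with a high ring fraction (scaffold-rich)."""
    return generate_fixture_corpus(
        FixtureSpec(n_molecules=60, ring_fraction=0.8, max_heavy_atoms=10, seed=11))


@pytest.fixture(scope="session")
def small_vocab(small_corpus) -> TokenVocabulary:
    return build_vocabulary(small_corpus)


@pytest.fixture()
def tiny_model() -> TransformerLM:
    cfg = ClmConfig(vocab_size=8, max_len=16, d_model=8, n_layers=2,
                    n_heads=2, d_ffn=16, dropout=0.0)
    return TransformerLM(cfg, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
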