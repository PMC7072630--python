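import numpy as np
import pytest

from pvpscm import LabeledDataset, ProteinSequence, ScoreCard, SyntheticConfig, generate


@pytest.fixture
def toy_dataset() -> LabeledDataset:
    """Tiny perfectly separable dataset: positives A-rich, negatives C-rich."""
    pos = ["AAAAAAAAAA", "AAAAACAAAA", "AAAAAAAACA"]
    neg = ["CCCCCCCCCC", "CCCCCACCCC", "CCCACCCCCC"]
    return LabeledDataset(
        [ProteinSequence(f"p{i}", s) for i, s in enumerate(pos)]
        + [ProteinSequence(f"n{i}", s) for i, s in enumerate(neg)],
        [1] * 3 + [0] * 3,
    )


@pytest.fixture
def uniform_card() -> ScoreCard:
    return ScoreCard(scores=np.full(400, 500.0))


@pytest.fixture
def aa_only_card() -> ScoreCard:
    """AA scores 1000, every other dipeptide 0."""
    scores = np.zeros(400)
    scores[0] = 1000.0
    return ScoreCard(scores=scores)


@pytest.fixture(scope="session")
def biased_dataset() -> LabeledDataset:
    """Moderate-size planted-signal dataset shared across tests."""
    return generate(
        SyntheticConfig(n_pos=60, n_neg=60, length_min=50, length_max=200,
                        bias=20.0, seed=11)
    )


def random_card(rng: np.random.Generator) -> ScoreCard:
    return ScoreCard(scores=rng.uniform(0.0, 1000.0, size=400))
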