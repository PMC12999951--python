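import numpy as np
import pytest

from repliskew import (
    CdsFeature,
    FeatureTable,
    Replicon,
    Strand,
    SyntheticConfig,
    simulate_replicon,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_replicon():
    # 48 bp, deterministic
    seq = "ATGGGCCATTGACGTGGGTACCCATGCACGTAGGCTTAACGGATCCTA"
    return Replicon("rep1", seq)


@pytest.fixture
def small_features():
    return FeatureTable(
        [
            CdsFeature("rep1", 0, 12, Strand.plus, 0),
            CdsFeature("rep1", 18, 30, Strand.minus, 0),
        ]
    )


@pytest.fixture(scope="session")
def synthetic_small():
    """200 kb annotated replicon with strong strand structure (cached per session)."""
    cfg = SyntheticConfig(length=200_000, beta=0.08, p_lead=0.9, seed=7)
    return simulate_replicon(cfg)


def random_replicon(rng, length, rid="rand"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Replicon(rid, seq)


def random_features(rng, length, n_features, rid="rand"):
    feats = []
    for _ in range(n_features):
        start = int(rng.integers(0, length - 4))
        end = int(rng.integers(start + 3, min(length, start + 60) + 1))
        strand = Strand.plus if rng.random() < 0.5 else Strand.minus
        frame = int(rng.integers(0, 3))
        feats.append(CdsFeature(rid, start, end, strand, frame))
    return FeatureTable(feats)
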