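import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from repeatskim.preprocess import ReadSet

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs distinct interior positions."""
    s = list(seq)
    pos = rng.choice(np.arange(1, len(s) - 1), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(0, 3)]
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def family_readset(rng):
    """Three well-separated families (400 bp windows of distinct 1.2 kb
    sources, light divergence) plus unrelated background reads."""
    reads = []
    for fam in range(3):
        src = random_seq(rng, 1200)
        for i in range(6):
            start = int(rng.integers(0, 800))
            read = mutate(rng, src[start : start + 400], n_subs=int(rng.integers(0, 8)))
            reads.append((f"f{fam}_r{i}", read))
    for i in range(8):
        reads.append((f"bg_r{i}", random_seq(rng, 400)))
    return ReadSet("fixture", reads)
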