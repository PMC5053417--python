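import random
import string

import numpy as np
import pytest

from pavscape.core_io import SeqRecord, reverse_complement
from pavscape.synthetic_data import (
    DivergenceConfig,
    ReadSimConfig,
    derive_accession,
    generate_ancestor,
    simulate_reads,
)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


@pytest.fixture(scope="session")
def small_pair():
    """A 100 kbp accession pair: 4 insertions + 4 deletions, default SNP
    background, no repeats.  Shared by mapping/ZCR/recovery tests."""
    ancestor = generate_ancestor(100_000, seed=11)
    cfg = DivergenceConfig(
        n_insertions=4, n_deletions=4, large_event_len_range=(150, 3000), seed=12
    )
    derived, registry = derive_accession(ancestor, cfg)
    acc_a = SeqRecord("accA", ancestor.record.sequence)
    acc_b = SeqRecord("accB", derived.sequence)
    return acc_a, acc_b, registry


@pytest.fixture(scope="session")
def small_pair_reads(small_pair):
    acc_a, acc_b, _ = small_pair
    sim_a = simulate_reads(acc_a, ReadSimConfig(coverage=25, seed=13))
    sim_b = simulate_reads(acc_b, ReadSimConfig(coverage=25, seed=14))
    return sim_a, sim_b
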