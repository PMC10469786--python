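import numpy as np
import pytest

from magtaxa import (PlantedCommunity, SequenceRecord, simulate_amplicon,
                     simulate_sequences)


@pytest.fixture(scope="session")
def planted_clade():
    """3 genera x 4 members, within-genus identity 99, between 88."""
    return simulate_sequences(3, 4, 1200, 99.0, 88.0, seed=11)


@pytest.fixture(scope="session")
def planted_clade_16():
    """16 genera x 4 members at the study's identity structure (97 / 88)."""
    return simulate_sequences(16, 4, 1200, 97.0, 88.0, seed=5)


@pytest.fixture()
def one_sample_community():
    comm = PlantedCommunity({"s1": "marine sediment"},
                            {"s1": {"repA": 0.10}}, {"s1": 1000})
    reps = [SequenceRecord("repA", "ACGT" * 375)]
    return comm, reps


def random_nucleotides(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
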