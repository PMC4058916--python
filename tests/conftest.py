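import numpy as np
import pytest

from cryptokin.genome_encoding import (
    EncodingParams,
    PhasedIndividual,
    ReferenceGenome,
)


@pytest.fixture
def toy_reference():
    """Two small chromosomes, 25 bp total genome."""
    return ReferenceGenome(
        "toy-1",
        (("chr1", 15), ("chr2", 10)),
        {"chr1": "ACGTACGTACGTACG", "chr2": "TTTTGGGGCC"},
    )


@pytest.fixture
def toy_params(toy_reference):
    return EncodingParams(segment_length=5, genome_length=toy_reference.total_length)


def make_individual(ind_id, chrom_haps):
    """chrom_haps: {chrom: (list hap1 positions, list hap2 positions)}."""
    return PhasedIndividual(
        ind_id,
        {
            c: (
                np.array(sorted(h1), dtype=np.int64),
                np.array(sorted(h2), dtype=np.int64),
            )
            for c, (h1, h2) in chrom_haps.items()
        },
    )


@pytest.fixture
def small_sim_config():
    """A deliberately tiny simulation for fast unit tests."""
    from cryptokin.pedigree_sim import SimConfig

    return SimConfig(
        genome_length=600_000,
        n_founders=12,
        generations=2,
        founder_model="iid_sites",
        mating_scheme="random",
        seq_error_rate=0.0,
        switch_error_rate=0.0,
        seed=11,
    )
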