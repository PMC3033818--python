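import numpy as np
import pytest

from hlacall import SimConfig, make_toy_dictionary, simulate_reads
from hlacall.simulator import ToyDictionarySpec

from helpers import make_dictionary


@pytest.fixture(scope="session")
def tiny_dict():
    """One locus, 3 alleles, single short exon with 3 polymorphic columns."""
    return make_dictionary(
        {
            "A": {
                "A*01:01": {"exon2": "ACGTACGTACGTACGTACGT"},
                "A*02:01": {"exon2": "ACGTACCTACGTACTTACGT"},
                "A*03:01": {"exon2": "ACGTACCTACGAACTTACGT"},
            }
        }
    )


@pytest.fixture(scope="session")
def toy_dictionary():
    """Default-regime toy dictionary + frequencies (shared, read-only)."""
    return make_toy_dictionary(seed=7)


@pytest.fixture(scope="session")
def small_dataset(toy_dictionary):
    """A small simulated pool used by several module tests."""
    dictionary, frequencies = toy_dictionary
    return simulate_reads(
        dictionary, frequencies,
        SimConfig(n_samples=8, mean_coverage=40, seed=101),
    )


@pytest.fixture(scope="session")
def clean_dataset(toy_dictionary):
    """Error-free simulated pool (exact barcodes and bases)."""
    dictionary, frequencies = toy_dictionary
    return simulate_reads(
        dictionary, frequencies,
        SimConfig(n_samples=8, mean_coverage=30, error_rate=0.0, seed=102),
    )
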