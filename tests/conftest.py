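import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from trirep.germline import builtin_library
from trirep.merge import merge_pairs
from trirep.pipeline import process_pairs
from trirep.simulate import ErrorModel, simulate_reads, simulate_repertoire


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture(scope="session")
def small_truth(library):
    """200-clonotype ground-truth repertoire."""
    return simulate_repertoire(library, 200, seed=11)


@pytest.fixture(scope="session")
def small_clean_run(library, small_truth):
    """Zero-noise end-to-end pipeline run at 20k reads."""
    reads = simulate_reads(small_truth, 20_000, ErrorModel.noiseless(), seed=12)
    return process_pairs(reads.pairs, library), reads


@pytest.fixture(scope="session")
def small_noisy_run(library, small_truth):
    """Default-noise end-to-end run at 20k reads."""
    reads = simulate_reads(small_truth, 20_000, ErrorModel(), seed=13)
    return process_pairs(reads.pairs, library), reads


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
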