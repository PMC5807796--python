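import numpy as np
import pytest

from lrcorrect import build_fm_index, build_msbwt


def random_reads(rng, n, min_len=40, max_len=100):
    bases = np.array(list("ACGT"))
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return ["".join(bases[rng.integers(0, 4, size=l)]) for l in lengths]


@pytest.fixture(scope="session")
def random_read_set():
    """A seeded 200-read random set with both index implementations."""
    rng = np.random.default_rng(42)
    reads = random_reads(rng, 200, 40, 100)
    bwt = build_msbwt(reads)
    return {
        "reads": reads,
        "bwt": bwt,
        "fm_bits": build_fm_index(bwt, "bitarray"),
        "fm_sampled": build_fm_index(bwt, "sampled", sample_rate=64),
    }
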