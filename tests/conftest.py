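import numpy as np
import pytest

from haplogen.io_formats import HaplotypeMatrix


def make_matrix(data, chrom="chr1", positions=None, start=1, spacing=10):
    """HaplotypeMatrix from a plain array with auto coordinates and donor-paired ids."""
    data = np.asarray(data, dtype=np.uint8)
    n, m = data.shape
    if positions is None:
        positions = np.arange(start, start + m * spacing, spacing)[:m]
    sample_ids = [f"S{i}_{s}" for i in range((n + 1) // 2) for s in ("A", "B")][:n]
    return HaplotypeMatrix(chrom=chrom, positions=np.asarray(positions, dtype=np.int64),
                           variant_ids=[f"v{j}" for j in range(m)],
                           sample_ids=sample_ids, data=data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    return make_matrix((rng.random((8, 20)) < 0.4).astype(np.uint8))
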