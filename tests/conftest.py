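import numpy as np
import pandas as pd
import pytest

from rarecnv.data import LogratioMatrix, ProbeIndex, Segmentation, SEGMENTATION_COLUMNS
from rarecnv.synth import make_probe_index


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_index() -> ProbeIndex:
    """12 probes on one chromosome, 1 kb apart."""
    return make_probe_index((("chr1", 12),))


@pytest.fixture
def two_chrom_index() -> ProbeIndex:
    return make_probe_index((("chr1", 10), ("chr2", 8)))


def make_matrix(values, probe_index, sample_prefix="S") -> LogratioMatrix:
    values = np.asarray(values, dtype=float)
    ids = [f"{sample_prefix}{i}" for i in range(values.shape[0])]
    return LogratioMatrix(values, ids, probe_index)


@pytest.fixture
def matrix_factory():
    return make_matrix


def make_segmentation(rows) -> Segmentation:
    df = pd.DataFrame(rows, columns=SEGMENTATION_COLUMNS)
    return Segmentation(df)


@pytest.fixture
def segmentation_factory():
    return make_segmentation
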