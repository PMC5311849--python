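import io

import numpy as np
import pytest

from multiburden.formats import (
    PhenotypeTable,
    Region,
    VariantRecord,
    read_sample_file,
)

SAMPLE_TEXT = """\
ID_1 ID_2 missing pheno_a pheno_b
0 0 0 P P
ind1 ind1 0 1.5 0.2
ind2 ind2 0 -0.3 NA
ind3 ind3 0 0.0 1.1
ind4 ind4 0 2.2 -0.7
"""


@pytest.fixture
def sample_table() -> PhenotypeTable:
    return read_sample_file(io.StringIO(SAMPLE_TEXT))


def make_variant(triplets, position=100, rs_id="rs1", snp_id="snp1"):
    """Helper: a VariantRecord from a list of (pAA, pAB, pBB) triplets."""
    probs = np.array(triplets, dtype=float)
    return VariantRecord(snp_id, rs_id, position, "A", "G", probs)


@pytest.fixture
def region() -> Region:
    return Region("GENE1", 1, 1000)
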