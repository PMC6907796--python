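import numpy as np
import pandas as pd
import pytest

from ebml.genotypes import GENOTYPE_COLUMNS


def make_calls(rows):
    """rows: (sample_id, population, locus_id, allele_a, allele_b, depth)."""
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


@pytest.fixture
def two_pop_calls():
    """Tiny two-population cohort at two loci."""
    return make_calls([
        ("s1", "AFR", "L1", 10, 10, 9),
        ("s2", "AFR", "L1", 10, 12, 8),
        ("s3", "AFR", "L1", 10, 10, 7),
        ("s4", "EUR", "L1", 10, 10, 9),
        ("s5", "EUR", "L1", 12, 12, 6),
        ("s1", "AFR", "L2", 20, 20, 10),
        ("s4", "EUR", "L2", 20, 22, 10),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
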