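import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from zfsex.sequences import DEFAULT_ASSAY, NucleotideSequence


@pytest.fixture
def assay():
    return DEFAULT_ASSAY


@pytest.fixture
def elephantine_reference(assay):
    """Synthetic template: forward primer + 30 bp insert carrying the
    X-probe site + reverse-complement of the reverse primer -> a 74 bp
    amplicon by construction."""
    insert = str(assay.probe_x) + "GATCGATCGATCGATCG"  # 13 + 17 = 30 bases
    assert len(insert) == 30
    seq = (
        str(assay.forward_primer)
        + insert
        + str(assay.reverse_primer.reverse_complement())
    )
    return NucleotideSequence(seq)


def logistic_trace(cq_star, plateau, cycles=40, efficiency=0.98):
    """Reference amplification curve: logistic crossing plateau/10 at
    cq_star, growth rate ln(1+efficiency) per cycle, zero baseline."""
    k = math.log(1.0 + efficiency)
    midpoint = cq_star + math.log(9.0) / k
    c = np.arange(1, cycles + 1, dtype=float)
    return plateau / (1.0 + np.exp(-k * (c - midpoint)))
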