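import numpy as np
import pytest

from heterotrace import TransitionScenario, simulate_transition
from heterotrace.core_io import VariantRecord, VariantTable


@pytest.fixture(scope="session")
def sim_wy():
    """Noise-free W-from-Y simulation shared across test modules."""
    return simulate_transition(TransitionScenario(seed=11))


@pytest.fixture(scope="session")
def sim_wx():
    return simulate_transition(TransitionScenario(seed=11, scenario="W_from_X"))


def make_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    genotypes=((0, 1), (0, 0)),
    qc=None,
):
    return VariantRecord(
        chrom, pos, ref, alt, np.array(genotypes, dtype=np.int8), qc or {}
    )


def make_table(records, n_samples=None):
    n = records[0].genotypes.shape[0] if records else (n_samples or 0)
    samples = [f"S{i}" for i in range(n)]
    return VariantTable(samples, records)
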