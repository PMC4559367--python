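import numpy as np
import pytest

from paralogdiverge import SimulationConfig, simulate_paralog_family
from paralogdiverge.seqcore import CodonAlignment, SequenceRecord


def make_alignment(rows, paralogs=None):
    """Codon alignment from (id, sequence) pairs with optional paralog labels."""
    meta = {}
    for rid, seq in rows:
        meta[rid] = SequenceRecord(
            id=rid, nucleotides=seq, species=rid,
            paralog=(paralogs or {}).get(rid, "unassigned"),
        )
    return CodonAlignment(records=tuple(rows), meta=meta)


@pytest.fixture(scope="session")
def small_family():
    """One deterministic two-clade family reused by several tests."""
    c1 = SimulationConfig(n_taxa=8, n_codons=240, omega=0.08, seed=11)
    c2 = SimulationConfig(n_taxa=8, n_codons=240, omega=0.03, seed=11)
    return simulate_paralog_family(c1, c2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
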