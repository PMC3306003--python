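from pathlib import Path

import numpy as np
import pytest

from exonscan.seqio import read_annotations, read_fasta

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def fixture_genome():
    """First shipped synthetic genome: (sequence, truth annotation)."""
    seq = read_fasta(FIXTURES / "genome1.fa")[0]
    ann = read_annotations(FIXTURES / "genome1.bed", "bed")[0]
    return seq, ann


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
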