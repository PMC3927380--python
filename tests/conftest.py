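import numpy as np
import pytest

from motifsampler.fixtures import fixture_tables
from motifsampler.io import SequenceRecord, SequenceSet


def seqset(*residues: str, ids=None) -> SequenceSet:
    """Build a SequenceSet from bare residue strings."""
    if ids is None:
        ids = [f"s{k + 1}" for k in range(len(residues))]
    return SequenceSet(tuple(SequenceRecord(i, r) for i, r in zip(ids, residues)))


@pytest.fixture(scope="session")
def reference():
    """The bundled published worked-example tables."""
    return fixture_tables()


@pytest.fixture()
def toy_planted():
    """3 sequences x 12 nt with an exact GGG planted in each, plus its starts.

    Small enough for exhaustive enumeration (10^3 start combinations).
    """
    rng = np.random.default_rng(7)
    seqs, starts = [], []
    for _ in range(3):
        s = "".join(rng.choice(list("ACGU"), 12, p=[0.3, 0.3, 0.2, 0.2]))
        pos = int(rng.integers(0, 10))
        seqs.append(s[:pos] + "GGG" + s[pos + 3 :])
        starts.append(pos + 1)
    return seqset(*seqs), tuple(starts)
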