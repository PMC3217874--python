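import numpy as np
import pytest

from tmclass.annotations_io import ProteinRecord
from tmclass.datasets import PFAM_TM_BENCHMARK


@pytest.fixture(scope="session")
def benchmark_rows():
    """The published per-domain TM benchmark rows."""
    return PFAM_TM_BENCHMARK


@pytest.fixture
def rng():
    return np.random.default_rng(20110)


@pytest.fixture
def toy_records():
    """Two small proteins with hand-placed TM segments."""
    r1 = ProteinRecord("P1", "MSTN" + "LLLVLLIALLLALLLALLL" + "GQDKRES")
    r1.add_segment(5, 23, "membrane-anchor")
    r2 = ProteinRecord("P2", "MA" + "RVLVDVLGGYEAAVNAASLT" + "KKQ" + "LLLIVALLILLLLLAILLP" + "DE")
    r2.add_segment(3, 22)
    r2.add_segment(26, 44)
    return [r1, r2]


def naive_hydrophobicity(seq, scale, window=19):
    """Brute-force double-loop oracle: mean of full-window sums."""
    seq = seq.upper()
    vals = [scale[aa] for aa in seq]
    if len(seq) <= window:
        return sum(vals)
    sums = []
    for i in range(len(seq) - window + 1):
        total = 0.0
        for j in range(i, i + window):
            total += vals[j]
        sums.append(total)
    return sum(sums) / len(sums)


def naive_complexity(seq, window=12, group_ivl=True):
    """Brute-force window/count/entropy enumeration oracle."""
    import math

    seq = seq.upper()

    def label(aa):
        if group_ivl and aa in "IVL":
            return "IVL"
        if aa in "ACDEFGHIKLMNPQRSTVWY":
            return aa
        return "?"

    def entropy(chunk):
        counts = {}
        for aa in chunk:
            counts[label(aa)] = counts.get(label(aa), 0) + 1
        total = len(chunk)
        return -sum((c / total) * math.log2(c / total) for c in counts.values())

    if len(seq) <= window:
        return entropy(seq)
    ents = [entropy(seq[i : i + window]) for i in range(len(seq) - window + 1)]
    return sum(ents) / len(ents)
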