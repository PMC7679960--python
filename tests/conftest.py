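import numpy as np
import pytest
from hypothesis import settings

from consmut.msa_io import AMINO_ACIDS, MSA, SequenceRecord

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

ALPHABET_WITH_GAP = AMINO_ACIDS + "-"


def make_msa(rows):
    """MSA from a list of (id, residues) pairs."""
    return MSA(records=tuple(SequenceRecord(id=i, residues=s) for i, s in rows))


def random_rows(rng: np.random.Generator, n_rows: int, n_cols: int, gap_p=0.1):
    """Random aligned rows; the first row ('REF') is kept gap-free so every
    column maps to a reference position."""
    symbols = list(ALPHABET_WITH_GAP)
    rows = []
    for i in range(n_rows):
        if i == 0:
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n_cols))
            rows.append(("REF", seq))
        else:
            probs = np.full(21, (1 - gap_p) / 20)
            probs[20] = gap_p
            seq = "".join(rng.choice(symbols, size=n_cols, p=probs))
            rows.append((f"seq{i}", seq))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def toy_msa():
    """10 rows; column 0 = {L x6, V x3, gap}, column 1 all A, WT row first.

    The reference (row 0) carries V at column 0, so f(cons)=6/9, f(WT)=3/9,
    ratio 2.0 there.
    """
    col0 = "VLLLLLLVV-"
    rows = [(f"s{i}", col0[i] + "A") for i in range(10)]
    return make_msa(rows)
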