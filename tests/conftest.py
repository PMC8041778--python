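import numpy as np
import pytest

from haced.seqio import Read, ReadPair, revcomp


def mk_read(seq: str, qual=None, rid: str = "r") -> Read:
    if qual is None:
        qual = [40] * len(seq)
    elif isinstance(qual, int):
        qual = [qual] * len(seq)
    return Read(rid, seq, np.asarray(qual))


def split_fragment(frag: str, read_len: int, rid: str = "p") -> ReadPair:
    """Cut an error-free fragment into an overlapping mate pair (Q40)."""
    r1 = frag[:read_len]
    r2 = revcomp(frag)[:read_len]
    return ReadPair(mk_read(r1, rid=rid), mk_read(r2, rid=rid))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
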