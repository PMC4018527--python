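import numpy as np
import pytest

from refless_qc.io_preprocess import ReadRecord


def make_read(bases: str, qual: int = 37, read_id: str = "r", mate: int | None = None,
              quals=None) -> ReadRecord:
    q = tuple(quals) if quals is not None else (qual,) * len(bases)
    return ReadRecord(read_id, bases, q, mate)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def tiling_reads(genome: str, read_len: int = 100, step: int = 1):
    """Error-free reads covering every start position of a genome."""
    return [
        make_read(genome[i : i + read_len], read_id=f"t{i}")
        for i in range(0, len(genome) - read_len + 1, step)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
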