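import numpy as np
import pytest

from barcodiv.seqio import Alignment, SampleMetadata, SequenceRecord


@pytest.fixture
def toy_alignment():
    """Four sequences, eight columns, with one singleton and one informative site."""
    return Alignment(
        [
            SequenceRecord("s1", "ACGTACGT"),
            SequenceRecord("s2", "ACGTACGT"),
            SequenceRecord("s3", "ACGTACGA"),  # singleton at col 8
            SequenceRecord("s4", "ATGTACGT"),  # singleton at col 2
        ]
    )


@pytest.fixture
def two_species_metadata():
    return [
        SampleMetadata("a1", "spA", "ingroup", "genuine"),
        SampleMetadata("a2", "spA", "ingroup", "genuine"),
        SampleMetadata("b1", "spB", "ingroup", "adulterant"),
        SampleMetadata("b2", "spB", "ingroup", "adulterant"),
    ]


def random_alignment(rng: np.random.Generator, n_seqs=None, length=None,
                     gap_prob=0.05, n_prob=0.02) -> Alignment:
    """A random gapped alignment guaranteed to keep >= 1 clean column."""
    n = n_seqs or int(rng.integers(3, 7))
    L = length or int(rng.integers(20, 60))
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n, L))]
    noise = rng.random((n, L))
    mat[noise < gap_prob] = "-"
    mat[(noise >= gap_prob) & (noise < gap_prob + n_prob)] = "N"
    mat[:, 0] = "A"  # keep column 1 clean so complete deletion is defined
    return Alignment([SequenceRecord(f"t{i}", "".join(row)) for i, row in enumerate(mat)])
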