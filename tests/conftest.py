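import numpy as np
import pytest

from proteotherm.seqio import CodonAlignment, ProteinAlignment, SequenceRecord


def codon_aln(*seqs: str, ids: list[str] | None = None) -> CodonAlignment:
    ids = ids or [f"sp{i+1}" for i in range(len(seqs))]
    return CodonAlignment(records=tuple(
        SequenceRecord(id=i, seq=s, alphabet="nucleotide") for i, s in zip(ids, seqs)
    ))


def protein_aln(*seqs: str, ids: list[str] | None = None) -> ProteinAlignment:
    ids = ids or [f"sp{i+1}" for i in range(len(seqs))]
    return ProteinAlignment(records=tuple(
        SequenceRecord(id=i, seq=s, alphabet="protein") for i, s in zip(ids, seqs)
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def helix20():
    from proteotherm.synthetic import make_ideal_helix

    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def helix20_asa(helix20):
    from proteotherm.structure import shrake_rupley_asa

    return shrake_rupley_asa(helix20)
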