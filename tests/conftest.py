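import numpy as np
import pytest

from barcodegap.seqio import SequenceRecord, SequenceSet

BASES = "ACGT"


def make_set(seqs, genus="Testus", species=None, regions=None, ids=None):
    """Build a SequenceSet from raw sequences with simple metadata."""
    n = len(seqs)
    species = species or ["sp01"] * n
    regions = regions or ["regionA"] * n
    ids = ids or [f"T{i + 1:03d}" for i in range(n)]
    genera = [genus] * n if isinstance(genus, str) else genus
    return SequenceSet(
        SequenceRecord(
            sample_id=ids[i], genus=genera[i], species_label=species[i],
            region=regions[i], sequence=seqs[i],
        )
        for i in range(n)
    )


def random_seq(rng, length):
    return "".join(rng.choice(list(BASES)) for _ in range(length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">Alburnus_thessalicus_Volvi_GFFB311-18\n"
        "ACGTACGTACGTACGTACGT\n"
        ">Alburnus_macedonicus_Doirani_GFFB100-17\n"
        "ACGTACGTACGAACGTACGT\n"
        ">Barbus_euboicus_Euboea_GFFB200-18\n"
        "ACGTTCGTACGTACGAACGT\n"
    )
    return path
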