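import random

import pytest

from zooclock.io_formats import SeqRecord
from zooclock.synthetic import SynthConfig, generate_transcripts, \
    generate_universe


@pytest.fixture(scope="session")
def small_universe():
    """Two species, noise off — shared across read-only tests."""
    return generate_universe(SynthConfig(n_species=2, seed=42))


@pytest.fixture(scope="session")
def small_universe_with_transcripts():
    u = generate_universe(SynthConfig(n_species=2, seed=42))
    transcripts, reverse_map = generate_transcripts(u)
    return u, transcripts, reverse_map


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_nt_record(rec_id: str, residues: str) -> SeqRecord:
    return SeqRecord(id=rec_id, residues=residues, alphabet="nucleotide")
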