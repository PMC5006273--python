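"""Shared fixtures: all test inputs are generated, none are downloaded."""

import pytest

from invsym import SequenceRecord, SyntheticSpec, generate_sequence


def write_fasta(path, records):
    """Write (id, residues) pairs as a FASTA file; returns the path."""
    with open(path, "w") as fh:
        for rec_id, residues in records:
            fh.write(f">{rec_id}\n{residues}\n")
    return path


@pytest.fixture
def fasta_factory(tmp_path):
    def make(records, name="test.fa"):
        return write_fasta(tmp_path / name, records)

    return make


@pytest.fixture(scope="session")
def iid_100k() -> SequenceRecord:
    return generate_sequence(SyntheticSpec(100_000, "iid", seed=101))


@pytest.fixture(scope="session")
def perfect_is_100k() -> SequenceRecord:
    return generate_sequence(SyntheticSpec(100_000, "perfect_is", seed=102))


@pytest.fixture(scope="session")
def skewed_300k() -> SequenceRecord:
    return generate_sequence(
        SyntheticSpec(300_000, "skewed", ta_ratio=1.4, gc_ratio=1.4, seed=103)
    )
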