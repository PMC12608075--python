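import textwrap

import pytest

from ovsize.read_io import ReadRecord


@pytest.fixture
def fasta_file(tmp_path):
    """Write records as a FASTA file and return its path."""

    def _write(records, name="reads.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def fastq_file(tmp_path):
    """Write (id, seq, qual) triples as a FASTQ file and return its path."""

    def _write(records, name="reads.fq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return path

    return _write


def make_reads(n, length=1000):
    """n dummy ReadRecords (no sequences) of the given length."""
    return [ReadRecord(id=f"r{i}", length=length) for i in range(n)]
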