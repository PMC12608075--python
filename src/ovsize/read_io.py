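"""Read input and sampling of query/target read sets.

Long-read genome-size estimation needs two (possibly identical) sets of
reads: a query set Q, for which per-read estimates are computed, and a
target set T against which overlaps are counted.  This module streams
FASTA/FASTQ records (plain or gzip-compressed) and draws Q and T by
single-pass reservoir sampling, so arbitrarily large read files are
handled in constant memory.
"""

from __future__ import annotations

import gzip
import io
import random
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "ReadSetPair",
    "Strategy",
    "ReadParseError",
    "EstimationImpossibleError",
    "stream_reads",
    "sample_read_sets",
    "write_fasta",
]


class ReadParseError(ValueError):
    """A FASTA/FASTQ record could not be parsed."""


class EstimationImpossibleError(RuntimeError):
    """Raised when no genome-size estimate can be produced from the input."""


class Strategy(str, Enum):
    """Sampling strategy: disjoint query/target sets or a single shared set."""

    TWO_SET = "2set"
    AVA = "ava"


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One sequenced read.

    Only the identifier and length are required by the estimator; the
    sequence is kept when available so reads can be written back out for
    an external aligner.
    """

    id: str
    length: int
    sequence: Optional[str] = None
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if self.length <= 0:
            raise ValueError(f"read {self.id!r}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"read {self.id!r}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(slots=True)
class ReadSetPair:
    """The sampled query set Q and target set T.

    Under the two-set strategy Q and T are disjoint by id; under ava they
    are the identical set.
    """

    queries: list[ReadRecord]
    targets: list[ReadRecord]
    strategy: Strategy
    seed: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.queries or not self.targets:
            raise ValueError("both Q and T must be non-empty")
        if self.strategy == Strategy.TWO_SET:
            shared = {r.id for r in self.queries} & {r.id for r in self.targets}
            if shared:
                raise ValueError(f"Q and T must be disjoint under 2set; shared ids: {sorted(shared)[:5]}")

    @property
    def mean_query_len(self) -> float:
        return sum(r.length for r in self.queries) / len(self.queries)

    @property
    def mean_target_len(self) -> float:
        return sum(r.length for r in self.targets) / len(self.targets)

    @property
    def total_target_len(self) -> int:
        return sum(r.length for r in self.targets)


def _open_text_auto(path: Union[str, Path]) -> IO[str]:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    try:
        magic = raw.read(2)
        raw.seek(0)
    except OSError:
        raw.close()
        raise
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def stream_reads(
    path: Union[str, Path], min_length: int = 0
) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA or FASTQ file, plain or gzipped.

    The format is auto-detected from the first byte of the (decompressed)
    stream: ``>`` for FASTA, ``@`` for FASTQ.  Records shorter than
    *min_length* are dropped; remaining records are yielded in file order
    with lengths computed from their sequences.

    Raises
    ------
    ReadParseError
        On a malformed record (e.g. a FASTQ entry whose quality string
        length differs from its sequence length), naming the offending
        record.
    """
    with _open_text_auto(path) as handle:
        first = handle.read(1)
        if first == "":
            return
        handle.seek(0)
        if first == ">":
            parser: Iterable[tuple] = SimpleFastaParser(handle)
            is_fastq = False
        elif first == "@":
            parser = FastqGeneralIterator(handle)
            is_fastq = True
        else:
            raise ReadParseError(
                f"{path}: cannot detect format (first byte {first!r}; expected '>' or '@')"
            )

        n_seen = 0
        try:
            for fields in parser:
                n_seen += 1
                if is_fastq:
                    title, seq, qual = fields
                else:
                    title, seq = fields
                    qual = None
                rid = title.split()[0] if title.split() else ""
                if not rid:
                    raise ReadParseError(f"{path}: record #{n_seen} has an empty id")
                if not seq:
                    raise ReadParseError(f"{path}: record {rid!r} (#{n_seen}) has an empty sequence")
                if qual is not None and len(qual) != len(seq):
                    raise ReadParseError(
                        f"{path}: record {rid!r} (#{n_seen}): quality length "
                        f"{len(qual)} != sequence length {len(seq)}"
                    )
                if len(seq) < min_length:
                    continue
                yield ReadRecord(id=rid, length=len(seq), sequence=seq, quality=qual)
        except ValueError as exc:
            if isinstance(exc, ReadParseError):
                raise
            # Biopython signals truncated/malformed records with ValueError
            raise ReadParseError(
                f"{path}: malformed record after record #{n_seen}: {exc}"
            ) from exc


def sample_read_sets(
    reads: Iterable[ReadRecord],
    strategy: Union[Strategy, str],
    n_query: int,
    n_target: int,
    seed: int = 42,
) -> ReadSetPair:
    """Draw the query and target sets by single-pass reservoir sampling.

    ``2set``: one combined reservoir of size ``n_query + n_target`` is
    drawn uniformly without replacement, shuffled, and split into Q
    (first *n_query*) and T (the rest), guaranteeing disjointness.
    ``ava``: a single reservoir of size *n_target* serves as both Q and T
    (*n_query* is ignored).

    If the input holds fewer reads than requested, all reads are used and
    a warning is recorded on the returned pair.  The result is a
    deterministic function of the input order, strategy, sizes and seed.
    """
    strategy = Strategy(strategy)
    if strategy == Strategy.TWO_SET:
        if n_query < 1 or n_target < 1:
            raise ValueError("2set requires n_query >= 1 and n_target >= 1")
        k = n_query + n_target
    else:
        if n_target < 2:
            raise ValueError("ava requires n_target >= 2")
        k = n_target

    rng = random.Random(seed)
    reservoir: list[ReadRecord] = []
    seen_ids: set[str] = set()
    n_seen = 0
    for rec in reads:
        if rec.id in seen_ids:
            raise ValueError(f"duplicate read id {rec.id!r} in input")
        seen_ids.add(rec.id)
        n_seen += 1
        if len(reservoir) < k:
            reservoir.append(rec)
        else:
            j = rng.randrange(n_seen)
            if j < k:
                reservoir[j] = rec

    if n_seen < 2:
        raise EstimationImpossibleError(
            f"only {n_seen} usable read(s); at least 2 are required"
        )

    notes: list[str] = []
    if n_seen < k:
        notes.append(
            f"requested {k} reads but input holds only {n_seen}; using all reads"
        )
        warnings.warn(notes[-1], stacklevel=2)

    rng.shuffle(reservoir)
    if strategy == Strategy.AVA:
        sample = reservoir
        return ReadSetPair(
            queries=sample, targets=sample, strategy=strategy, seed=seed,
            warnings=notes,
        )

    # 2set: split the shuffled reservoir; if short, keep both sides non-empty
    # at roughly the requested proportions.
    if n_seen >= k:
        nq = n_query
    else:
        nq = max(1, min(len(reservoir) - 1, round(len(reservoir) * n_query / k)))
    queries = reservoir[:nq]
    targets = reservoir[nq:]
    return ReadSetPair(
        queries=queries, targets=targets, strategy=strategy, seed=seed,
        warnings=notes,
    )


def write_fasta(records: Sequence[ReadRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA with their original ids (for the aligner backend)."""
    with open(path, "w") as out:
        for rec in records:
            if rec.sequence is None:
                raise ValueError(f"read {rec.id!r} has no sequence to write")
            out.write(f">{rec.id}\n{rec.sequence}\n")
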