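"""Synthetic genomes and reads with exact ground-truth overlaps.

Every stage of the estimator is testable without external data or an
aligner: reads are placed uniformly at random on a genome of known size,
true pairwise overlap counts are computed from the placement intervals,
and "perfect" PAF records are emitted for each truly overlapping pair so
the PAF-consuming pipeline can be checked against the interval truth.

A circular-genome mode is provided because on a circle the uniform-
placement model has no edge effects, making the expected-overlap-count
formula exact; linear mode is retained to exhibit the (small) edge
effect near genome ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from .overlaps import PafRecord

__all__ = [
    "FixedLength",
    "LognormalLength",
    "SimConfig",
    "Placement",
    "simulate_placements",
    "true_overlap_counts",
    "true_overlap_counts_bruteforce",
    "emit_synthetic_paf",
    "emit_sequences",
    "write_placements_tsv",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True, slots=True)
class FixedLength:
    """All reads have the same length."""

    length: int


@dataclass(frozen=True, slots=True)
class LognormalLength:
    """Lognormal read lengths (in bp), clipped to [min_length, max_length].

    ``mu`` and ``sigma`` are the parameters of the underlying normal on
    the log scale, as in numpy's lognormal.
    """

    mu: float
    sigma: float
    min_length: int
    max_length: int


LengthModel = Union[FixedLength, LognormalLength]


@dataclass(slots=True)
class SimConfig:
    """Study conditions for one simulated sequencing run."""

    genome_size: int
    n_reads: int
    length_model: LengthModel
    circular: bool = True
    ot: int = 100
    seed: int = 42
    emit_sequences: bool = False
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads < 2:
            raise ValueError("n_reads must be >= 2")
        max_len = (
            self.length_model.length
            if isinstance(self.length_model, FixedLength)
            else self.length_model.max_length
        )
        if self.genome_size <= max_len:
            raise ValueError(
                f"genome_size ({self.genome_size}) must exceed the maximum "
                f"possible read length ({max_len})"
            )
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True, slots=True)
class Placement:
    """Ground truth: one read's interval [start, start+length) on the genome.

    In circular mode the interval may wrap past the origin (start is
    always in [0, genome_size)).
    """

    read_id: str
    start: int
    length: int
    strand: str


def _draw_lengths(model: LengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, FixedLength):
        return np.full(n, model.length, dtype=np.int64)
    raw = rng.lognormal(mean=model.mu, sigma=model.sigma, size=n)
    return np.clip(np.round(raw), model.min_length, model.max_length).astype(np.int64)


def simulate_placements(config: SimConfig) -> list[Placement]:
    """Place reads uniformly at random on the genome.

    Linear mode draws each start uniformly from the genome_size - length
    positions that keep the read on the genome; circular mode draws from
    all genome_size positions, wrapping past the origin.  Strands are
    uniform.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _draw_lengths(config.length_model, config.n_reads, rng)
    if int(lengths.max()) >= config.genome_size:
        raise ValueError("drawn read length >= genome size")
    if config.circular:
        starts = rng.integers(0, config.genome_size, size=config.n_reads)
    else:
        starts = rng.integers(0, config.genome_size - lengths)
    strands = np.where(rng.random(config.n_reads) < 0.5, "+", "-")
    width = len(str(config.n_reads))
    return [
        Placement(
            read_id=f"read_{i:0{width}d}",
            start=int(starts[i]),
            length=int(lengths[i]),
            strand=str(strands[i]),
        )
        for i in range(config.n_reads)
    ]


def _max_arc_intersection(
    a: Placement, b: Placement, genome_size: Optional[int], circular: bool
) -> tuple[int, int, int]:
    """Longest contiguous intersection of two (possibly wrapping) intervals.

    Returns (length, x, y): the intersection [x, y) in the unwrapped
    frame of ``a`` (a's interval is [a.start, a.start + a.length) without
    modular reduction; b is shifted by -GS/0/+GS to find the maximal
    contiguous arc).  length <= 0 means no intersection.
    """
    sa, ea = a.start, a.start + a.length
    offsets = (0,) if not circular else (-genome_size, 0, genome_size)
    best = (0, 0, 0)
    for off in offsets:
        sb, eb = b.start + off, b.start + b.length + off
        x, y = max(sa, sb), min(ea, eb)
        if y - x > best[0]:
            best = (y - x, x, y)
    return best


def true_overlap_counts(
    placements: Sequence[Placement],
    ot: int,
    circular: bool,
    genome_size: Optional[int] = None,
) -> dict[str, int]:
    """Count, for each read, how many other reads truly overlap it by >= ot.

    Sorted-sweep implementation, O(n log n + k) for k overlapping pairs.
    A pair counts (for both reads) when the longest contiguous
    intersection arc of their intervals is at least ``ot`` bases.
    """
    if circular and genome_size is None:
        raise ValueError("genome_size is required in circular mode")
    counts = {p.read_id: 0 for p in placements}
    for i, j in _overlapping_pairs_sweep(placements, ot, circular, genome_size):
        counts[placements[i].read_id] += 1
        counts[placements[j].read_id] += 1
    return counts


def _overlapping_pairs_sweep(
    placements: Sequence[Placement],
    ot: int,
    circular: bool,
    genome_size: Optional[int],
) -> Iterator[tuple[int, int]]:
    """Yield index pairs (i < j) whose intervals overlap by >= ot bases.

    Intervals are swept in start order; in circular mode a +GS-shifted
    copy of every interval is added so seam-crossing overlaps are found,
    and pairs are deduplicated.
    """
    items: list[tuple[int, int, int]] = []  # (start, end, original index)
    for idx, p in enumerate(placements):
        items.append((p.start, p.start + p.length, idx))
    n_base = len(items)
    if circular:
        for idx, p in enumerate(placements):
            items.append((p.start + genome_size, p.start + p.length + genome_size, idx))
    items.sort()

    emitted: set[tuple[int, int]] = set()
    for k, (s1, e1, i1) in enumerate(items):
        limit = e1 - ot
        for m in range(k + 1, len(items)):
            s2, e2, i2 = items[m]
            if s2 > limit:
                break
            if i1 == i2:
                continue
            if min(e1, e2) - s2 >= ot:
                key = (i1, i2) if i1 < i2 else (i2, i1)
                if key not in emitted:
                    emitted.add(key)
                    yield key


def true_overlap_counts_bruteforce(
    placements: Sequence[Placement],
    ot: int,
    circular: bool,
    genome_size: Optional[int] = None,
) -> dict[str, int]:
    """O(n^2) reference implementation of :func:`true_overlap_counts`."""
    if circular and genome_size is None:
        raise ValueError("genome_size is required in circular mode")
    counts = {p.read_id: 0 for p in placements}
    n = len(placements)
    for i in range(n):
        for j in range(i + 1, n):
            length, _, _ = _max_arc_intersection(
                placements[i], placements[j], genome_size, circular
            )
            if length >= ot:
                counts[placements[i].read_id] += 1
                counts[placements[j].read_id] += 1
    return counts


def emit_synthetic_paf(
    placements: Sequence[Placement],
    ot: int,
    circular: bool,
    genome_size: Optional[int] = None,
) -> Iterator[PafRecord]:
    """One perfect PAF record per truly overlapping pair.

    Read coordinates are derived from the interval intersection mapped
    into each read's own frame ('-' strand placements store the reverse
    complement, so genome coordinates reverse); nmatch == alnlen ==
    overlap length; mapq 60.  Containment pairs yield records that the
    containment classifier flags as contained.
    """
    if circular and genome_size is None:
        raise ValueError("genome_size is required in circular mode")
    for i, j in _overlapping_pairs_sweep(placements, ot, circular, genome_size):
        a, b = placements[i], placements[j]
        length, x, y = _max_arc_intersection(a, b, genome_size, circular)
        # x, y are in a's unwrapped frame; recover b's frame offset
        sa, ea = a.start, a.start + a.length
        off = 0
        if circular:
            for cand in (-genome_size, 0, genome_size):
                sb, eb = b.start + cand, b.start + b.length + cand
                if min(ea, eb) - max(sa, sb) == length and max(sa, sb) == x:
                    off = cand
                    break
        sb, eb = b.start + off, b.start + b.length + off

        if a.strand == "+":
            qstart, qend = x - sa, y - sa
        else:
            qstart, qend = ea - y, ea - x
        if b.strand == "+":
            tstart, tend = x - sb, y - sb
        else:
            tstart, tend = eb - y, eb - x
        yield PafRecord(
            qname=a.read_id,
            qlen=a.length,
            qstart=qstart,
            qend=qend,
            strand="+" if a.strand == b.strand else "-",
            tname=b.read_id,
            tlen=b.length,
            tstart=tstart,
            tend=tend,
            nmatch=length,
            alnlen=length,
            mapq=60,
        )


def _random_genome(genome_size: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=genome_size))


def _extract_read(genome: str, p: Placement, circular: bool) -> str:
    gs = len(genome)
    end = p.start + p.length
    if end <= gs:
        seq = genome[p.start : end]
    else:
        if not circular:
            raise ValueError(f"read {p.read_id} runs off a linear genome")
        seq = genome[p.start :] + genome[: end - gs]
    if p.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    return seq


def emit_sequences(
    placements: Sequence[Placement],
    config: SimConfig,
    genome_out: Union[str, Path],
    reads_out: Union[str, Path],
) -> None:
    """Write a random genome FASTA and the reads extracted at each placement.

    '-' strand reads are reverse-complemented; substitution errors are
    applied at ``config.error_rate`` (no indels, so coordinates stay
    exact).  Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 0xC0FFEE])
    genome = _random_genome(config.genome_size, rng)
    with open(genome_out, "w") as gfh:
        gfh.write(">genome\n")
        for k in range(0, len(genome), 80):
            gfh.write(genome[k : k + 80] + "\n")

    bases = "ACGT"
    with open(reads_out, "w") as rfh:
        for p in placements:
            seq = _extract_read(genome, p, config.circular)
            if config.error_rate > 0:
                chars = list(seq)
                hits = np.nonzero(rng.random(len(chars)) < config.error_rate)[0]
                for pos in hits:
                    old = chars[pos]
                    alternatives = bases.replace(old.upper(), "")
                    chars[pos] = alternatives[rng.integers(0, len(alternatives))]
                seq = "".join(chars)
            rfh.write(f">{p.read_id}\n{seq}\n")


def write_placements_tsv(
    placements: Sequence[Placement], path: Union[str, Path]
) -> None:
    """Truth table: read_id, start, length, strand (tab-separated, with header)."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tlength\tstrand\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.start}\t{p.length}\t{p.strand}\n")
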