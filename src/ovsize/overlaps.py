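"""Overlap evidence: PAF records, containment filtering, distinct-partner counts.

The estimator consumes, for each query read q, the number of *distinct*
target reads overlapping q.  This module parses PAF (Pairwise mApping
Format) streams, optionally drives an external minimap2 all-vs-all run,
classifies containments ("internal matches", where one read lies fully
within the other) and tallies counts.

Counting is over distinct read pairs, not alignment records: minimap2's
chaining can emit several records for one read pair, which would inflate
the expected-count model if counted naively.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from .read_io import ReadSetPair, Strategy, write_fasta

__all__ = [
    "PafRecord",
    "PafParseError",
    "OverlapParams",
    "OverlapCounts",
    "Containment",
    "AlignerError",
    "parse_paf",
    "classify_containment",
    "count_overlaps",
    "generate_overlaps",
]

PAF_COLUMNS = 12


class PafParseError(ValueError):
    """A PAF line violates the 12-column format."""


class AlignerError(RuntimeError):
    """The external aligner backend failed or is unavailable."""


class Containment(str, Enum):
    NONE = "none"
    QUERY_CONTAINED = "query_contained"
    TARGET_CONTAINED = "target_contained"


@dataclass(frozen=True, slots=True)
class PafRecord:
    """One overlap line: the 12 mandatory PAF columns.

    Coordinates are 0-based half-open.  Target coordinates are always on
    the target's forward strand; the strand column gives the relative
    orientation.  ``mapq`` and ``nmatch`` are parsed for diagnostics but
    play no role in counting.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"{self.qname}->{self.tname}: bad query interval "
                f"[{self.qstart},{self.qend}) for length {self.qlen}"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(
                f"{self.qname}->{self.tname}: bad target interval "
                f"[{self.tstart},{self.tend}) for length {self.tlen}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.nmatch > self.alnlen:
            raise ValueError(
                f"{self.qname}->{self.tname}: nmatch {self.nmatch} > alnlen {self.alnlen}"
            )

    def to_line(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.qname, self.qlen, self.qstart, self.qend, self.strand,
                self.tname, self.tlen, self.tstart, self.tend,
                self.nmatch, self.alnlen, self.mapq,
            )
        )


@dataclass(slots=True)
class OverlapParams:
    """Knobs shared by overlap generation and counting.

    ``min_overlap_ot`` is a single parameter serving two roles by
    construction: the model's minimum-overlap threshold OT and the
    aligner's minimum chaining score (minimap2 ``-m``), so the evidence
    and the expected-count formula stay consistent.
    """

    min_overlap_ot: int = 100
    filter_internal: bool = False
    containment_tolerance: int = 0
    platform_preset: str = "ont"  # or "pacbio"
    threads: int = 1
    use_min_ref: bool = False

    def __post_init__(self) -> None:
        if self.min_overlap_ot < 1:
            raise ValueError("min_overlap_ot must be >= 1")
        if self.platform_preset not in ("ont", "pacbio"):
            raise ValueError(f"unknown platform preset {self.platform_preset!r}")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass(slots=True)
class OverlapCounts:
    """Per-query-read count of distinct overlapping target reads.

    ``n_targets_effective`` is |T \\ {q}| (|T| - 1 under ava, |T| under
    2set) and ``mean_target_len_effective`` the matching mean target
    length with q excluded — the quantities the expected-count formula
    needs per query.
    """

    counts: dict[str, int]
    n_targets_effective: dict[str, int]
    mean_target_len_effective: dict[str, float]
    diagnostics: dict[str, int] = field(default_factory=dict)


def parse_paf(stream: Union[IO[str], Iterable[str]]) -> Iterator[PafRecord]:
    """Parse a PAF text stream, yielding records in input order.

    Lines need at least 12 tab-separated fields; optional SAM-style tags
    beyond column 12 are ignored.  Malformed lines raise
    :class:`PafParseError` with the line number.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < PAF_COLUMNS:
            raise PafParseError(
                f"line {lineno}: expected >= {PAF_COLUMNS} tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            rec = PafRecord(
                qname=fields[0],
                qlen=int(fields[1]),
                qstart=int(fields[2]),
                qend=int(fields[3]),
                strand=fields[4],
                tname=fields[5],
                tlen=int(fields[6]),
                tstart=int(fields[7]),
                tend=int(fields[8]),
                nmatch=int(fields[9]),
                alnlen=int(fields[10]),
                mapq=int(fields[11]),
            )
        except ValueError as exc:
            raise PafParseError(f"line {lineno}: {exc}") from exc
        yield rec


def classify_containment(rec: PafRecord, tolerance: int = 0) -> Containment:
    """Classify an overlap record as a containment ("internal match") or not.

    The standard assembly-graph end-overhang test, on strand-normalized
    coordinates: for a '-' strand record the target interval is flipped to
    the query's frame (tstart' = tlen - tend, tend' = tlen - tstart).  The
    query is contained when its unaligned overhangs on both ends fit
    within the target's (up to *tolerance* bp), and symmetrically for the
    target.  When both hold (mutual containment), the shorter read is
    reported as the contained one.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if rec.strand == "-":
        tstart, tend = rec.tlen - rec.tend, rec.tlen - rec.tstart
    else:
        tstart, tend = rec.tstart, rec.tend
    q_head, q_tail = rec.qstart, rec.qlen - rec.qend
    t_head, t_tail = tstart, rec.tlen - tend

    q_in_t = q_head <= t_head + tolerance and q_tail <= t_tail + tolerance
    t_in_q = t_head <= q_head + tolerance and t_tail <= q_tail + tolerance
    if q_in_t and t_in_q:
        return Containment.QUERY_CONTAINED if rec.qlen <= rec.tlen else Containment.TARGET_CONTAINED
    if q_in_t:
        return Containment.QUERY_CONTAINED
    if t_in_q:
        return Containment.TARGET_CONTAINED
    return Containment.NONE


def count_overlaps(
    records: Iterable[PafRecord],
    pair: ReadSetPair,
    params: Optional[OverlapParams] = None,
) -> OverlapCounts:
    """Tally, for every query read, the number of distinct overlapping targets.

    Each unordered read pair {a, b} with a != b contributes at most one
    count, regardless of how many alignment records it produced or which
    set served as the aligner's reference (records are normalized so the
    Q-side read is the query).  Self pairs contribute nothing.  Under ava
    a pair increments both members' counts.  When ``filter_internal`` is
    set, containment records are discarded before counting.  Every q in Q
    appears in the result, including with count 0.
    """
    if params is None:
        params = OverlapParams()

    qids = {r.id for r in pair.queries}
    tids = {r.id for r in pair.targets}
    ava = pair.strategy == Strategy.AVA

    counts: dict[str, int] = {r.id: 0 for r in pair.queries}
    seen: set[tuple[str, str]] = set()
    diag = {
        "n_records": 0,
        "n_unresolved": 0,
        "n_self": 0,
        "n_intra_set": 0,
        "n_containment_filtered": 0,
        "n_duplicate_pair": 0,
    }

    for rec in records:
        diag["n_records"] += 1
        a, b = rec.qname, rec.tname
        if a == b:
            diag["n_self"] += 1
            continue
        if params.filter_internal and classify_containment(
            rec, params.containment_tolerance
        ) is not Containment.NONE:
            diag["n_containment_filtered"] += 1
            continue

        if ava:
            if a not in qids or b not in qids:
                diag["n_unresolved"] += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                diag["n_duplicate_pair"] += 1
                continue
            seen.add(key)
            counts[a] += 1
            counts[b] += 1
        else:
            # normalize so the Q-side read is the query
            if a in qids and b in tids:
                q, t = a, b
            elif b in qids and a in tids:
                q, t = b, a
            elif (a in qids and b in qids) or (a in tids and b in tids):
                diag["n_intra_set"] += 1
                continue
            else:
                diag["n_unresolved"] += 1
                continue
            key = (q, t)
            if key in seen:
                diag["n_duplicate_pair"] += 1
                continue
            seen.add(key)
            counts[q] += 1

    total_t = pair.total_target_len
    n_t = len(pair.targets)
    tlen_by_id = {r.id: r.length for r in pair.targets}
    n_eff: dict[str, int] = {}
    mean_eff: dict[str, float] = {}
    for q in pair.queries:
        if ava:
            n_eff[q.id] = n_t - 1
            mean_eff[q.id] = (total_t - tlen_by_id[q.id]) / (n_t - 1)
        else:
            n_eff[q.id] = n_t
            mean_eff[q.id] = total_t / n_t

    return OverlapCounts(
        counts=counts,
        n_targets_effective=n_eff,
        mean_target_len_effective=mean_eff,
        diagnostics=diag,
    )


_PRESETS = {"ont": "ava-ont", "pacbio": "ava-pb"}


def generate_overlaps(
    pair: ReadSetPair,
    params: OverlapParams,
    backend: str = "paf_file",
    paf_path: Optional[Union[str, Path]] = None,
) -> Iterator[PafRecord]:
    """Produce overlap records from a PAF file or an external minimap2 run.

    ``paf_file``: stream records from *paf_path*.  ``external_minimap2``:
    write the read sets as FASTA and run minimap2 in all-vs-all mode with
    the platform preset (ava-ont / ava-pb) and minimum chaining score set
    to OT, streaming its PAF output.  With ``use_min_ref`` the smaller of
    the two sets is written as the reference; downstream counts are
    invariant to the choice because counting normalizes record direction.
    """
    if backend == "paf_file":
        if paf_path is None:
            raise ValueError("paf_file backend requires paf_path")
        with open(paf_path) as fh:
            yield from parse_paf(fh)
        return
    if backend != "external_minimap2":
        raise ValueError(f"unknown backend {backend!r}")

    exe = shutil.which("minimap2")
    if exe is None:
        raise AlignerError(
            "minimap2 not found on PATH; install it (e.g. via bioconda) or "
            "supply a precomputed PAF file instead"
        )

    preset = _PRESETS[params.platform_preset]
    with tempfile.TemporaryDirectory(prefix="ovsize_mm2_") as tmp:
        tmp = Path(tmp)
        if pair.strategy == Strategy.AVA:
            reads_fa = tmp / "reads.fa"
            write_fasta(pair.targets, reads_fa)
            ref_fa, qry_fa = reads_fa, reads_fa
        else:
            ref_set, qry_set = pair.targets, pair.queries
            if params.use_min_ref and len(pair.queries) < len(pair.targets):
                ref_set, qry_set = pair.queries, pair.targets
            ref_fa, qry_fa = tmp / "ref.fa", tmp / "qry.fa"
            write_fasta(ref_set, ref_fa)
            write_fasta(qry_set, qry_fa)

        cmd = [exe, "-x", preset, "-m", str(params.min_overlap_ot),
               "-t", str(params.threads)]
        if pair.strategy != Strategy.AVA:
            # ava presets suppress "dual" hits (each pair reported in one
            # lexicographic orientation only); with distinct query/reference
            # files that silently drops half the Q-T pairs.
            cmd += ["--dual=yes"]
        cmd += [str(ref_fa), str(qry_fa)]
        proc = subprocess.Popen(
            cmd, stdout=subprocess.PIPE, stderr=subprocess.PIPE, text=True
        )
        assert proc.stdout is not None
        try:
            yield from parse_paf(proc.stdout)
        finally:
            stderr = proc.stderr.read() if proc.stderr else ""
            ret = proc.wait()
        if ret != 0:
            raise AlignerError(
                f"minimap2 exited with status {ret}: {stderr.strip()[-500:]}"
            )
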