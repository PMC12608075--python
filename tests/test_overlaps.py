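"""PAF parsing, containment classification and distinct-partner counting."""

import io

import pytest

from ovsize.overlaps import (
    Containment,
    OverlapParams,
    PafParseError,
    PafRecord,
    classify_containment,
    count_overlaps,
    generate_overlaps,
    parse_paf,
)
from ovsize.read_io import ReadRecord, ReadSetPair, Strategy
from ovsize.simulate import (
    FixedLength,
    SimConfig,
    emit_synthetic_paf,
    simulate_placements,
    true_overlap_counts_bruteforce,
)
from conftest import make_reads


def rec(qname="q1", qlen=1000, qstart=50, qend=950, strand="+",
        tname="t1", tlen=1200, tstart=0, tend=900, nmatch=850, alnlen=900, mapq=60):
    return PafRecord(qname, qlen, qstart, qend, strand,
                     tname, tlen, tstart, tend, nmatch, alnlen, mapq)


class TestParsePaf:
    def test_field_mapping(self):
        line = "q1\t1000\t50\t950\t+\tt1\t1200\t0\t900\t850\t900\t60\n"
        (r,) = parse_paf(io.StringIO(line))
        assert r == rec()

    def test_empty_stream(self):
        assert list(parse_paf(io.StringIO(""))) == []

    def test_tags_beyond_column_12_ignored(self):
        line = "q1\t1000\t50\t950\t+\tt1\t1200\t0\t900\t850\t900\t60\ttp:A:S\tcm:i:5\n"
        (r,) = parse_paf(io.StringIO(line))
        assert r.mapq == 60

    @pytest.mark.parametrize("line,msg", [
        ("q1\t1000\t50\t950\t+\tt1\t1200\t0\t900\t850\t900", "12"),
        ("q1\tX\t50\t950\t+\tt1\t1200\t0\t900\t850\t900\t60", "line 1"),
        ("q1\t1000\t950\t50\t+\tt1\t1200\t0\t900\t850\t900\t60", "interval"),
    ])
    def test_malformed_lines_raise_with_line_number(self, line, msg):
        with pytest.raises(PafParseError, match=msg):
            list(parse_paf(io.StringIO(line + "\n")))

    def test_emit_parse_round_trip(self):
        cfg = SimConfig(genome_size=50_000, n_reads=200,
                        length_model=FixedLength(800), circular=True, seed=3)
        records = list(emit_synthetic_paf(simulate_placements(cfg), 100, True, 50_000))
        assert records
        text = "".join(r.to_line() + "\n" for r in records)
        assert list(parse_paf(io.StringIO(text))) == records


class TestClassifyContainment:
    def test_full_span_query_is_contained(self):
        r = rec(qlen=1000, qstart=0, qend=1000, tlen=5000, tstart=2000,
                tend=3000, nmatch=1000, alnlen=1000)
        assert classify_containment(r, 0) is Containment.QUERY_CONTAINED

    def test_dovetail_overlap_is_not_contained(self):
        r = rec(qlen=1000, qstart=800, qend=1000, tlen=1000, tstart=0,
                tend=200, nmatch=200, alnlen=200)
        assert classify_containment(r, 0) is Containment.NONE

    def test_full_span_target_is_contained(self):
        r = rec(qlen=5000, qstart=2000, qend=3000, tlen=1000, tstart=0,
                tend=1000, nmatch=1000, alnlen=1000)
        assert classify_containment(r, 0) is Containment.TARGET_CONTAINED

    def test_mutual_containment_reports_shorter_read(self):
        r = rec(qlen=900, qstart=0, qend=900, tlen=1000, tstart=0,
                tend=1000, nmatch=900, alnlen=1000)
        assert classify_containment(r, 0) is Containment.QUERY_CONTAINED

    def test_minus_strand_coordinates_are_normalized(self):
        # query fully aligned to the reverse strand of a longer target
        r = rec(qlen=500, qstart=0, qend=500, strand="-", tlen=2000,
                tstart=700, tend=1200, nmatch=500, alnlen=500)
        assert classify_containment(r, 0) is Containment.QUERY_CONTAINED

    def test_tolerance_admits_small_overhangs(self):
        # query head overhang (5) exceeds the target's (2) by 3 bp
        r = rec(qlen=1000, qstart=5, qend=1000, tlen=1200, tstart=2,
                tend=997, nmatch=900, alnlen=995)
        assert classify_containment(r, 0) is Containment.NONE
        assert classify_containment(r, 3) is Containment.QUERY_CONTAINED

    def test_classifier_matches_interval_oracle_on_simulated_truth(self):
        """On perfect PAF from known placements, the record classifier agrees
        with direct interval containment for every emitted pair."""
        import numpy as np
        from ovsize.simulate import Placement

        rng = np.random.default_rng(11)
        gs = 200_000
        placements = []
        # background reads
        for i in range(170):
            ln = int(rng.integers(500, 3000))
            placements.append(Placement(f"bg{i}", int(rng.integers(0, gs)), ln,
                                        "+" if rng.random() < 0.5 else "-"))
        # 30 reads placed strictly inside one of the first 30 backgrounds
        n_true = 0
        for i in range(30):
            host = placements[i]
            if host.length < 400:
                continue
            ln = host.length // 2
            start = (host.start + host.length // 4) % gs
            placements.append(Placement(f"in{i}", start, ln,
                                        "+" if rng.random() < 0.5 else "-"))
            n_true += 1
        assert n_true == 30

        def interval_contained(a, b):
            # a inside b (or b inside a), on the circle
            for off in (-gs, 0, gs):
                sa, ea = a.start + off, a.start + a.length + off
                if sa >= b.start and ea <= b.start + b.length:
                    return True
                sb, eb = b.start + off, b.start + b.length + off
                if sb >= a.start and eb <= a.start + a.length:
                    return True
            return False

        by_id = {p.read_id: p for p in placements}
        n_contained = 0
        for r in emit_synthetic_paf(placements, 100, True, gs):
            expected = interval_contained(by_id[r.qname], by_id[r.tname])
            got = classify_containment(r, 0) is not Containment.NONE
            assert got == expected, f"{r.qname} vs {r.tname}"
            n_contained += got
        assert n_contained >= 30  # the 30 constructed plus any by chance


def ava_pair(ids, length=1000):
    reads = [ReadRecord(i, length) for i in ids]
    return ReadSetPair(queries=reads, targets=reads, strategy=Strategy.AVA, seed=0)


def two_set_pair(qids, tids, length=1000):
    return ReadSetPair(
        queries=[ReadRecord(i, length) for i in qids],
        targets=[ReadRecord(i, length) for i in tids],
        strategy=Strategy.TWO_SET,
        seed=0,
    )


def simple_rec(q, t, qlen=1000, tlen=1000):
    return PafRecord(q, qlen, 0, 500, "+", t, tlen, 500, 1000, 500, 500, 60)


class TestCountOverlaps:
    def test_ava_dedup_and_self_exclusion(self):
        pair = ava_pair(["r1", "r2", "r3"])
        records = [simple_rec("r1", "r2"), simple_rec("r2", "r1"),
                   simple_rec("r1", "r1")]
        counts = count_overlaps(records, pair)
        assert counts.counts == {"r1": 1, "r2": 1, "r3": 0}
        assert counts.n_targets_effective == {"r1": 2, "r2": 2, "r3": 2}

    def test_two_set_repeated_records_count_once(self):
        pair = two_set_pair(["q1"], ["t1", "t2"])
        records = [simple_rec("q1", "t1")] * 3
        counts = count_overlaps(records, pair)
        assert counts.counts == {"q1": 1}
        assert counts.diagnostics["n_duplicate_pair"] == 2
        assert counts.n_targets_effective == {"q1": 2}

    def test_swapped_direction_normalized_to_query_side(self):
        pair = two_set_pair(["q1"], ["t1"])
        counts = count_overlaps([simple_rec("t1", "q1")], pair)
        assert counts.counts == {"q1": 1}

    def test_unresolvable_and_intra_set_records_are_diagnostics(self):
        pair = two_set_pair(["q1", "q2"], ["t1"])
        records = [simple_rec("x", "y"), simple_rec("q1", "q2")]
        counts = count_overlaps(records, pair)
        assert counts.counts == {"q1": 0, "q2": 0}
        assert counts.diagnostics["n_unresolved"] == 1
        assert counts.diagnostics["n_intra_set"] == 1

    def test_duplicating_every_record_changes_nothing(self):
        cfg = SimConfig(genome_size=60_000, n_reads=300,
                        length_model=FixedLength(700), circular=True, seed=5)
        pl = simulate_placements(cfg)
        pair = ava_pair([p.read_id for p in pl], 700)
        records = list(emit_synthetic_paf(pl, 100, True, 60_000))
        once = count_overlaps(records, pair)
        twice = count_overlaps(records + records, pair)
        assert once.counts == twice.counts

    def test_containment_filter_never_increases_counts(self):
        cfg = SimConfig(genome_size=40_000, n_reads=300,
                        length_model=FixedLength(600), circular=True, seed=9)
        pl = simulate_placements(cfg)
        pair = ava_pair([p.read_id for p in pl], 600)
        records = list(emit_synthetic_paf(pl, 100, True, 40_000))
        plain = count_overlaps(records, pair, OverlapParams(filter_internal=False))
        filt = count_overlaps(records, pair, OverlapParams(filter_internal=True))
        assert all(filt.counts[k] <= plain.counts[k] for k in plain.counts)

    def test_counts_match_bruteforce_oracle_on_simulated_paf(self):
        cfg = SimConfig(genome_size=100_000, n_reads=500,
                        length_model=FixedLength(1000), circular=True, seed=42)
        pl = simulate_placements(cfg)
        pair = ava_pair([p.read_id for p in pl], 1000)
        records = emit_synthetic_paf(pl, 100, True, 100_000)
        counts = count_overlaps(records, pair)
        oracle = true_overlap_counts_bruteforce(pl, 100, True, 100_000)
        assert counts.counts == oracle

    def test_reference_swap_invariance(self):
        """Counts are identical whichever set served as the aligner reference:
        swapping every record's query/target fields leaves counts unchanged."""
        cfg = SimConfig(genome_size=80_000, n_reads=400,
                        length_model=FixedLength(900), circular=True, seed=13)
        pl = simulate_placements(cfg)
        ids = [p.read_id for p in pl]
        pair = two_set_pair(ids[:150], ids[150:], 900)
        records = list(emit_synthetic_paf(pl, 100, True, 80_000))
        swapped = [
            PafRecord(r.tname, r.tlen, r.tstart, r.tend, r.strand,
                      r.qname, r.qlen, r.qstart, r.qend, r.nmatch, r.alnlen, r.mapq)
            for r in records
        ]
        assert count_overlaps(records, pair).counts == \
            count_overlaps(swapped, pair).counts


class TestGenerateOverlaps:
    def test_paf_file_backend_streams_parsed_records(self, tmp_path):
        records = [simple_rec(f"q{i}", f"t{i}") for i in range(5)]
        paf = tmp_path / "ov.paf"
        paf.write_text("".join(r.to_line() + "\n" for r in records))
        pair = two_set_pair([f"q{i}" for i in range(5)], [f"t{i}" for i in range(5)])
        out = list(generate_overlaps(pair, OverlapParams(), "paf_file", paf))
        assert out == records

    def test_paf_file_backend_requires_path(self):
        pair = two_set_pair(["q1"], ["t1"])
        with pytest.raises(ValueError, match="paf_path"):
            list(generate_overlaps(pair, OverlapParams(), "paf_file", None))

    def test_unknown_backend_rejected(self):
        pair = two_set_pair(["q1"], ["t1"])
        with pytest.raises(ValueError, match="backend"):
            list(generate_overlaps(pair, OverlapParams(), "bowtie", None))
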