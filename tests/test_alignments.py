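"""Pileup layout, coverage, CIGAR arithmetic, MM/ML decoding, policies."""

import numpy as np
import pytest

from genoscene.alignments import (AlignedRead, apply_read_policies,
                                  assign_rows, base_at, cigar_spans,
                                  compute_coverage, decode_modifications,
                                  encode_modifications, find_insertions,
                                  find_softclip_markers, parse_cigar,
                                  query_span_on_read, read_to_ref_path)
from genoscene.errors import FormatError, PolicyError, TagError
from genoscene.genome import Region


def _read(cigar, start=0, seq=None, strand="+", tags=None, name="r",
          mapq=60, flags=None):
    ops = parse_cigar(cigar)
    if flags is None:
        flags = 16 if strand == "-" else 0
    return AlignedRead(name=name, refName="chr1", start=start, cigar=ops,
                       strand=strand, flags=flags, mapq=mapq, seq=seq,
                       tags=tags or {})


def _max_depth(intervals):
    """Brute-force maximum overlap depth (sweep over endpoints)."""
    events = []
    for start, end in intervals:
        events.append((start, 1))
        events.append((end, -1))
    events.sort()
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best


class TestAssignRows:
    def test_empty(self):
        assert assign_rows([]).rowCount == 0

    def test_first_fit_reuses_rows(self):
        layout = assign_rows([("a", 0, 10), ("b", 5, 15), ("c", 12, 20)])
        assert [layout.rowOf[k] for k in "abc"] == [0, 1, 0]
        assert layout.rowCount == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(FormatError):
            assign_rows([("a", 5, 10), ("b", 0, 3)])

    def test_rowcount_equals_max_overlap_depth(self):
        rng = np.random.default_rng(13)
        starts = np.sort(rng.integers(0, 5000, size=1000))
        lengths = rng.integers(1, 300, size=1000)
        intervals = sorted(
            ((f"r{i}", int(s), int(s + l))
             for i, (s, l) in enumerate(zip(starts, lengths))),
            key=lambda t: (t[1], -(t[2] - t[1]), t[0]))
        layout = assign_rows(intervals)
        assert layout.rowCount == _max_depth([(s, e) for _, s, e in intervals])
        # no same-row overlap
        rows = {}
        for uid, s, e in intervals:
            for s2, e2 in rows.get(layout.rowOf[uid], []):
                assert e <= s2 or s >= e2
            rows.setdefault(layout.rowOf[uid], []).append((s, e))

    def test_padding_separates_rows(self):
        layout = assign_rows([("a", 0, 10), ("b", 12, 20)], paddingBp=5)
        assert layout.rowOf["a"] != layout.rowOf["b"]


class TestComputeCoverage:
    def test_single_read_block(self):
        signal = compute_coverage([_read("10M")], Region("chr1", 0, 20), 1)
        assert signal.values == [1.0] * 10 + [0.0] * 10

    def test_deletion_adds_no_depth(self):
        signal = compute_coverage([_read("5M5D5M")], Region("chr1", 0, 15), 1)
        assert signal.values == [1.0] * 5 + [0.0] * 5 + [1.0] * 5

    def test_mass_conservation_against_per_base_oracle(self):
        rng = np.random.default_rng(17)
        region = Region("chr1", 0, 3000)
        reads, per_base = [], np.zeros(region.length)
        for _ in range(200):
            start = int(rng.integers(0, 2500))
            parts, pos = [], start
            for op in ("M", "D", "M"):
                n = int(rng.integers(1, 120))
                parts.append(f"{n}{op}")
                if op in "MD":
                    if op == "M":
                        per_base[max(pos, 0):min(pos + n, region.length)] += 1
                    pos += n
            reads.append(_read("".join(parts), start=start))
        bin_bp = 25
        signal = compute_coverage(reads, region, bin_bp)
        mass = sum(
            v * len(per_base[i * bin_bp:(i + 1) * bin_bp])
            for i, v in enumerate(signal.values))
        assert mass == pytest.approx(per_base.sum())


class TestCigarArithmetic:
    @pytest.mark.parametrize("cigar,expected", [
        ("10M", (10, 10, 0, 0)),
        ("5M2I3M", (8, 10, 0, 0)),
        ("10H20M5S", (20, 25, 10, 5)),
    ])
    def test_spans(self, cigar, expected):
        assert cigar_spans(parse_cigar(cigar)) == expected

    @pytest.mark.parametrize("cigar,start,expected", [
        ("20S30M", 100, [(100, 20, "left")]),
        ("30M20S", 100, [(130, 20, "right")]),
        ("5S10M5S", 100, [(100, 5, "left"), (110, 5, "right")]),
        ("30M", 100, []),
    ])
    def test_softclip_markers(self, cigar, start, expected):
        assert find_softclip_markers(_read(cigar, start=start)) == expected

    def test_insertions_with_threshold(self):
        read = _read("5M3I5M")
        assert find_insertions(read, 1) == [(5, 3)]
        assert find_insertions(read, 4) == []

    def test_insertions_match_walk_oracle(self):
        rng = np.random.default_rng(23)
        ops = "MIDNS"
        for _ in range(50):
            cigar = [(ops[rng.integers(0, 5)], int(rng.integers(1, 30)))
                     for _ in range(rng.integers(1, 10))]
            cigar = [("M", 5)] + cigar + [("M", 5)]  # keep clips interior-free
            cigar = [(op, n) for op, n in cigar if op != "S"]
            read = AlignedRead("r", "chr1", 100, cigar)
            # oracle: walk reference-consuming ops
            want, rpos = [], 100
            for op, n in cigar:
                if op == "I":
                    want.append((rpos, n))
                if op in "MDN=X":
                    rpos += n
            assert find_insertions(read, 1) == want

    @pytest.mark.parametrize("cigar,strand,expected", [
        ("10H20M5S", "+", (10, 30)),
        ("10H20M5S", "-", (5, 25)),
        ("35M", "+", (0, 35)),
    ])
    def test_query_span_on_read(self, cigar, strand, expected):
        assert query_span_on_read(_read(cigar, strand=strand)) == expected

    def test_read_to_ref_path_consumption_laws(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            middle = [("MID"[rng.integers(0, 3)], int(rng.integers(1, 50)))
                      for _ in range(rng.integers(1, 12))]
            cigar = [("S", 3)] + [("M", 2)] + middle + [("M", 2), ("S", 4)]
            read = AlignedRead("r", "chr1", 50, cigar)
            path = read_to_ref_path(read)
            ref_span, _, _, _ = cigar_spans(cigar)
            assert sum(s[3] - s[2] for s in path
                       if s[4] in ("match", "del")) == ref_span
            aligned_q = sum(n for op, n in cigar if op in "MI=X")
            assert sum(s[1] - s[0] for s in path
                       if s[4] in ("match", "ins")) == aligned_q
            # contiguity on both axes
            for a, b in zip(path, path[1:]):
                assert a[1] == b[0] and a[3] == b[2]

    def test_read_to_ref_path_simple(self):
        path = read_to_ref_path(_read("5M3I5M", start=100))
        assert path == [(0, 5, 100, 105, "match"), (5, 8, 105, 105, "ins"),
                        (8, 13, 105, 110, "match")]


class TestModificationDecoding:
    def test_forward_hand_walk(self):
        read = _read("5M", seq="CCCCC", tags={"MM": "C+m,2,0;"})
        assert [c.readPos for c in decode_modifications(read)] == [2, 3]

    def test_reverse_hand_walk_from_three_prime(self):
        read = _read("5M", seq="GGGGG", strand="-", tags={"MM": "C+m,0;"})
        calls = decode_modifications(read)
        assert [c.readPos for c in calls] == [4]
        assert calls[0].canonicalBase == "C"

    def test_ml_likelihood_scaling(self):
        read = _read("3M", seq="CAT", tags={"MM": "C+m,0;", "ML": [255]})
        call = decode_modifications(read)[0]
        assert call.likelihood == pytest.approx(255.5 / 256)

    def test_overflow_is_malformed(self):
        read = _read("3M", seq="CAT", tags={"MM": "C+m,5;"})
        with pytest.raises(TagError):
            decode_modifications(read)

    def test_round_trip_on_simulated_reads_both_strands(self):
        from genoscene.fixtures import simulate_modified_reads

        reads = simulate_modified_reads(200, seed=31)
        assert {r.strand for r in reads} == {"+", "-"}
        for read in reads:
            calls = decode_modifications(read)
            mm, ml = encode_modifications(read, calls)
            assert mm == read.tags["MM"]
            assert ml == list(read.tags["ML"])


class TestReadPolicies:
    def _fixture_reads(self):
        bases = ["A", "C", "G", "T"]
        reads = [
            _read("10M", start=95, seq=bases[i] * 10, name=f"b{i}",
                  tags={"HP": 1 + i % 2})
            for i in range(4)
        ]
        reads.append(_read("5M10D5M", start=95, seq="A" * 10, name="del"))
        reads.append(_read("10M", start=200, seq="A" * 10, name="far"))
        reads.append(_read("10M", start=95, seq="A" * 10, name="unmapped",
                           flags=0x4))
        return reads

    def test_filter_excludes_flag(self):
        reads = self._fixture_reads()
        kept = apply_read_policies(reads, filterSpec={"flags_exclude": 0x4})
        assert all(r.name != "unmapped" for r, _ in kept)

    def test_sort_by_base_at_position_groups_acgt_del_ref(self):
        reads = self._fixture_reads()
        out = apply_read_policies(reads, sortSpec={"by": "base"}, at=100)
        names = [r.name for r, _ in out]
        assert names.index("b0") < names.index("b1") < names.index("b2") \
            < names.index("b3") < names.index("del") < names.index("far")

    def test_color_by_strand_two_classes(self):
        reads = [_read("5M", seq="AAAAA"), _read("5M", seq="AAAAA", strand="-")]
        out = apply_read_policies(reads, colorSpec={"by": "strand"})
        assert [c for _, c in out] == ["strand_fwd", "strand_rev"]

    def test_unknown_policy_rejected(self):
        with pytest.raises(PolicyError):
            apply_read_policies([], filterSpec={"bogus": 1})
        with pytest.raises(PolicyError):
            apply_read_policies([], sortSpec={"by": "bogus"})

    def test_base_at_reports_deletion(self):
        assert base_at(_read("5M10D5M", start=0, seq="A" * 10), 7) == "del"
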