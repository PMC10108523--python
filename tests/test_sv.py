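"""Breakend grammar, mate pairing, BEDPE, table filtering, split evidence."""

import numpy as np
import pytest

from genoscene.errors import FilterExpressionError, FormatError
from genoscene.features import VariantFeature
from genoscene.sv import (LEFT_OF_POS, RIGHT_OF_POS, Breakend, SVEvent,
                          breakpoint_panels, filter_table, format_breakend,
                          gather_split_evidence, pair_mates,
                          parse_breakend_alt, read_bedpe, read_starfusion,
                          sv_events)
from genoscene.table import to_table


def _variant(uid, chrom, pos, alt, info=None):
    return VariantFeature(uniqueId=uid, refName=chrom, start=pos - 1,
                          end=pos, ref="N", alts=(alt,), info=info or {})


class TestBreakendGrammar:
    # the four VCF 4.2 bracket forms and their join orientations
    CASES = [
        ("A[chr5:100[", LEFT_OF_POS, RIGHT_OF_POS, "", "first"),
        ("A]chr5:100]", LEFT_OF_POS, LEFT_OF_POS, "", "first"),
        ("]chr5:100]A", RIGHT_OF_POS, LEFT_OF_POS, "", "last"),
        ("[chr5:100[A", RIGHT_OF_POS, RIGHT_OF_POS, "", "last"),
        ("ATT[chr5:100[", LEFT_OF_POS, RIGHT_OF_POS, "TT", "first"),
        ("]chr5:100]TTA", RIGHT_OF_POS, LEFT_OF_POS, "TT", "last"),
    ]

    @pytest.mark.parametrize("alt,join,mate_join,inserted,anchor_side", CASES)
    def test_four_forms(self, alt, join, mate_join, inserted, anchor_side):
        b = parse_breakend_alt(alt, "chr1", 50)
        assert (b.joinSide, b.mateJoinSide) == (join, mate_join)
        assert (b.mateChrom, b.matePos) == ("chr5", 100)
        assert b.insertedSeq == inserted
        assert b.anchorBase == "A"

    @pytest.mark.parametrize("alt", ["A[chr5:100", "T", "<DEL>", "[x[A]y]"])
    def test_malformed_alt_rejected(self, alt):
        with pytest.raises(FormatError):
            parse_breakend_alt(alt, "chr1", 50)

    def test_format_parse_identity_randomized(self):
        rng = np.random.default_rng(41)
        sides = [LEFT_OF_POS, RIGHT_OF_POS]
        bases = "ACGT"
        for _ in range(1000):
            b = Breakend(
                chrom="chr1", pos=int(rng.integers(1, 10**8)),
                anchorBase=bases[rng.integers(0, 4)],
                insertedSeq="".join(
                    bases[i] for i in rng.integers(0, 4,
                                                   size=rng.integers(0, 5))),
                mateChrom=f"chr{rng.integers(1, 23)}",
                matePos=int(rng.integers(1, 10**8)),
                joinSide=sides[rng.integers(0, 2)],
                mateJoinSide=sides[rng.integers(0, 2)],
            )
            alt = format_breakend(b)
            b2 = parse_breakend_alt(alt, b.chrom, b.pos)
            assert format_breakend(b2) == alt
            assert (b2.joinSide, b2.mateJoinSide, b2.mateChrom, b2.matePos,
                    b2.insertedSeq, b2.anchorBase) == \
                (b.joinSide, b.mateJoinSide, b.mateChrom, b.matePos,
                 b.insertedSeq, b.anchorBase)


    def test_format_parse_identity_property(self):
        from hypothesis import given, settings, strategies as st

        side = st.sampled_from([LEFT_OF_POS, RIGHT_OF_POS])

        @settings(derandomize=True, max_examples=200, deadline=None)
        @given(st.integers(1, 10**9), st.sampled_from("ACGTN"),
               st.text(alphabet="ACGT", max_size=8),
               st.integers(1, 10**9), side, side)
        def check(pos, anchor, inserted, mate_pos, join, mate_join):
            b = Breakend("chr1", pos, anchor, inserted, "chrM", mate_pos,
                         join, mate_join)
            alt = format_breakend(b)
            assert format_breakend(parse_breakend_alt(alt, "chr1", pos)) == alt

        check()


class TestPairMates:
    def test_mutual_mateids_give_one_event(self):
        variants = [
            _variant("a", "chr1", 100, "A[chr2:500[", {"MATEID": "b"}),
            _variant("b", "chr2", 500, "]chr1:100]T", {"MATEID": "a"}),
        ]
        events = pair_mates(variants)
        assert len(events) == 1
        assert events[0].end1 == ("chr1", 99)
        assert events[0].end2 == ("chr2", 499)

    def test_reciprocal_coordinates_without_mateid(self):
        variants = [
            _variant("a", "chr1", 100, "A[chr2:500["),
            _variant("b", "chr2", 500, "]chr1:100]T"),
        ]
        assert len(pair_mates(variants)) == 1

    def test_lone_breakend_is_single_ended(self, caplog):
        events = pair_mates([_variant("a", "chr1", 100, "A[chr2:500[")])
        assert len(events) == 1
        assert events[0].end2 is None

    def test_symbolic_records_become_two_ended_events(self):
        v = _variant("d", "chr1", 1000, "<DEL>",
                     {"SVTYPE": "DEL", "END": 2000})
        v.end = 2000
        events = sv_events([v])
        assert [(e.kind, e.end1, e.end2) for e in events] == \
            [("DEL", ("chr1", 999), ("chr1", 1999))]


class TestBedpeAndFusion:
    def test_midpoints_and_extra_columns(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text("chr1\t100\t200\tchr2\t400\t600\tevt1\t7\t+\t-\n")
        events = read_bedpe(str(path))
        assert len(events) == 1
        assert events[0].end1 == ("chr1", 150)
        assert events[0].end2 == ("chr2", 500)
        assert events[0].info["name"] == "evt1"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text("")
        assert read_bedpe(str(path)) == []

    def test_five_columns_rejected(self, tmp_path):
        path = tmp_path / "a.bedpe"
        path.write_text("chr1\t100\t200\tchr2\t400\n")
        with pytest.raises(FormatError):
            read_bedpe(str(path))

    def test_starfusion_breakpoints(self, tmp_path):
        path = tmp_path / "fus.tsv"
        path.write_text(
            "#FusionName\tLeftBreakpoint\tRightBreakpoint\n"
            "AA--BB\tchr1:1000:+\tchr9:2000:-\n")
        events = read_starfusion(str(path))
        assert events[0].end1 == ("chr1", 999)
        assert events[0].end2 == ("chr9", 1999)
        assert events[0].kind == "fusion"


def _mixed_events():
    events = [
        SVEvent(id=f"b{i}", kind="BND", end1=("chr1", 100 * i),
                end2=("chr2", 5000 + i)) for i in range(3)
    ]
    events.append(SVEvent(id="d1", kind="DEL", end1=("chr3", 9),
                          end2=("chr3", 99)))
    events.append(SVEvent(id="v1", kind="INV", end1=("chr1", 2000),
                          end2=("chr1", 3000)))
    return events


class TestFilterTable:
    def test_type_equality(self):
        table = to_table(_mixed_events())
        assert len(filter_table(table, "type=BND")) == 3

    def test_empty_expression_is_identity(self):
        table = to_table(_mixed_events())
        assert len(filter_table(table, "")) == len(table)

    def test_conjunction_equals_sequential_filters(self):
        table = to_table(_mixed_events())
        combined = filter_table(table, "refName~chr start>150")
        sequential = filter_table(filter_table(table, "refName~chr"),
                                  "start>150")
        assert combined.rows == sequential.rows
        # and both agree with the brute-force predicate
        want = [row for row in table.rows
                if "chr" in str(row[1]) and row[2] is not None and row[2] > 150]
        assert combined.rows == want

    def test_bare_token_substring(self):
        table = to_table(_mixed_events())
        assert len(filter_table(table, "chr3")) == 1

    def test_unknown_column_rejected(self):
        table = to_table(_mixed_events())
        with pytest.raises(FilterExpressionError):
            filter_table(table, "bogus=1")

    def test_bad_number_rejected(self):
        table = to_table(_mixed_events())
        with pytest.raises(FilterExpressionError):
            filter_table(table, "start>abc")


class TestBreakpointPanels:
    def test_centered_windows(self):
        event = SVEvent(id="e", kind="BND", end1=("chr1", 5000),
                        end2=("chr5", 7000))
        pa, pb = breakpoint_panels(event, 1000)
        assert (pa.regions[0].start, pa.regions[0].end) == (4500, 5500)
        assert (pb.regions[0].refName, pb.regions[0].start,
                pb.regions[0].end) == ("chr5", 6500, 7500)

    def test_clamped_at_sequence_start(self):
        event = SVEvent(id="e", kind="BND", end1=("chr1", 100),
                        end2=("chr5", 7000))
        pa, _ = breakpoint_panels(event, 1000)
        assert pa.regions[0].start == 0

    def test_single_ended_event_has_no_second_panel(self):
        event = SVEvent(id="e", kind="BND", end1=("chr1", 5000), end2=None)
        pa, pb = breakpoint_panels(event, 1000)
        assert pb is None


class TestGatherSplitEvidence:
    def _split_read(self, name="r1"):
        from genoscene.alignments import AlignedRead, parse_cigar

        a = AlignedRead(name, "chr1", 4800, parse_cigar("200M300S"),
                        seq="A" * 500)
        b = AlignedRead(name, "chr5", 7000, parse_cigar("200S300M"),
                        seq="A" * 500, flags=0x800)
        return [a, b]

    def test_split_read_yields_one_connector_at_breakpoints(self):
        event = SVEvent(id="e", kind="BND", end1=("chr1", 4999),
                        end2=("chr5", 7000))
        connectors = gather_split_evidence(self._split_read(), event,
                                           windowBp=2000)
        assert len(connectors) == 1
        c = connectors[0]
        assert c.endA == (0, "chr1", 5000)
        assert c.endB == (1, "chr5", 7000)

    def test_unsplit_read_contributes_nothing(self):
        from genoscene.alignments import AlignedRead, parse_cigar

        event = SVEvent(id="e", kind="BND", end1=("chr1", 4999),
                        end2=("chr5", 7000))
        read = AlignedRead("solo", "chr1", 4900, parse_cigar("100M"))
        assert gather_split_evidence([read], event, windowBp=2000) == []

    def test_three_segments_give_two_connectors(self):
        from genoscene.alignments import AlignedRead, parse_cigar

        event = SVEvent(id="e", kind="BND", end1=("chr1", 5000),
                        end2=("chr5", 7000))
        reads = [
            AlignedRead("r", "chr1", 4900, parse_cigar("100M200S")),
            AlignedRead("r", "chr5", 7000, parse_cigar("100S100M100S"),
                        flags=0x800),
            AlignedRead("r", "chr1", 5000, parse_cigar("200S100M"),
                        flags=0x800),
        ]
        assert len(gather_split_evidence(reads, event, windowBp=2000)) == 2
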