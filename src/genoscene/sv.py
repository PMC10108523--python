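"""Structural-variant toolkit: breakend grammar, mate pairing, BEDPE and
fusion ingestion, table filtering, and breakpoint-split evidence gathering.

A VCF breakend (BND) describes one side of a novel adjacency with bracket
notation: ``t[p[``, ``t]p]``, ``]p]t``, ``[p[t``.  The bracket orientation
and the side the anchored bases sit on determine which piece of each
chromosome is retained at the junction; :func:`parse_breakend_alt` maps the
four forms onto (joinSide, mateJoinSide) and :func:`format_breakend` is its
exact inverse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import FilterExpressionError, FormatError
from .features import VariantFeature
from .genome import Assembly, DisplayedRegions, Region

log = logging.getLogger("genoscene.sv")

LEFT_OF_POS = "left_of_pos"
RIGHT_OF_POS = "right_of_pos"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 1-based, as in VCF
    anchorBase: str
    insertedSeq: str
    mateChrom: str
    matePos: int  # 1-based
    joinSide: str  # side of pos retained at the junction
    mateJoinSide: str
    mateId: Optional[str] = None


@dataclass
class SVEvent:
    id: str
    kind: str  # BND / DEL / DUP / INV / TRA / BEDPE / fusion
    end1: tuple[str, int]  # (refName, 0-based position)
    end2: Optional[tuple[str, int]]
    info: dict = field(default_factory=dict)
    sourceRow: Optional[object] = None
    joinSide1: Optional[str] = None
    joinSide2: Optional[str] = None

    def __post_init__(self) -> None:
        # canonical storage: end1 <= end2 by (refName, pos)
        if self.end2 is not None and (self.end2 < self.end1):
            self.end1, self.end2 = self.end2, self.end1
            self.joinSide1, self.joinSide2 = self.joinSide2, self.joinSide1


# ---------------------------------------------------------------------------
# breakend grammar

_BND_FORMS = [
    # (regex, t side, joinSide, mateJoinSide)
    (re.compile(r"^(?P<t>[A-Za-z*.]+)\[(?P<chrom>[^\[\]:]+):(?P<pos>\d+)\[$"),
     "first", LEFT_OF_POS, RIGHT_OF_POS),   # t[p[
    (re.compile(r"^(?P<t>[A-Za-z*.]+)\](?P<chrom>[^\[\]:]+):(?P<pos>\d+)\]$"),
     "first", LEFT_OF_POS, LEFT_OF_POS),    # t]p]
    (re.compile(r"^\](?P<chrom>[^\[\]:]+):(?P<pos>\d+)\](?P<t>[A-Za-z*.]+)$"),
     "last", RIGHT_OF_POS, LEFT_OF_POS),    # ]p]t
    (re.compile(r"^\[(?P<chrom>[^\[\]:]+):(?P<pos>\d+)\[(?P<t>[A-Za-z*.]+)$"),
     "last", RIGHT_OF_POS, RIGHT_OF_POS),   # [p[t
]


def is_breakend_alt(alt: str) -> bool:
    return "[" in alt or "]" in alt


def parse_breakend_alt(altText: str, chrom: str, pos: int,
                       mateId: Optional[str] = None) -> Breakend:
    """Parse one of the four VCF 4.2 breakend ALT forms.

    ``pos`` is 1-based (as in the VCF record).  The anchor base is the t
    character adjacent to the local breakpoint; any remaining t characters
    are novel inserted sequence.
    """
    for regex, t_side, join, mate_join in _BND_FORMS:
        m = regex.match(altText)
        if m is None:
            continue
        t = m.group("t")
        if t_side == "first":
            anchor, inserted = t[0], t[1:]
        else:
            anchor, inserted = t[-1], t[:-1]
        return Breakend(
            chrom=chrom, pos=pos, anchorBase=anchor, insertedSeq=inserted,
            mateChrom=m.group("chrom"), matePos=int(m.group("pos")),
            joinSide=join, mateJoinSide=mate_join, mateId=mateId,
        )
    raise FormatError(f"ALT {altText!r} is not a valid breakend")


def format_breakend(b: Breakend) -> str:
    """Inverse of :func:`parse_breakend_alt`."""
    p = f"{b.mateChrom}:{b.matePos}"
    if b.joinSide == LEFT_OF_POS:
        t = b.anchorBase + b.insertedSeq
        if b.mateJoinSide == RIGHT_OF_POS:
            return f"{t}[{p}["
        return f"{t}]{p}]"
    t = b.insertedSeq + b.anchorBase
    if b.mateJoinSide == LEFT_OF_POS:
        return f"]{p}]{t}"
    return f"[{p}[{t}"


# ---------------------------------------------------------------------------
# event assembly


def _breakends_of(variant: VariantFeature) -> list[Breakend]:
    out = []
    mate_ids = variant.info.get("MATEID")
    if isinstance(mate_ids, str):
        mate_ids = [mate_ids]
    for i, alt in enumerate(variant.alts):
        if not is_breakend_alt(alt):
            continue
        mate_id = None
        if mate_ids:
            mate_id = mate_ids[min(i, len(mate_ids) - 1)]
        out.append(parse_breakend_alt(alt, variant.refName, variant.pos, mate_id))
    return out


def pair_mates(variants: Sequence[VariantFeature]) -> list[SVEvent]:
    """Pair BND records into junction events.

    Pairing uses MATEID when present, else a reciprocal coordinate match
    ((chrom, pos, mateChrom, matePos) mirrored).  Unpaired breakends become
    single-ended events and are logged.
    """
    records: list[tuple[VariantFeature, Breakend]] = []
    for v in variants:
        for b in _breakends_of(v):
            records.append((v, b))
    by_id = {v.uniqueId: (v, b) for v, b in records}
    by_coord: dict[tuple, list[str]] = {}
    for v, b in records:
        by_coord.setdefault((b.chrom, b.pos, b.mateChrom, b.matePos), []).append(
            v.uniqueId
        )
    consumed: set[str] = set()
    events: list[SVEvent] = []
    for v, b in records:
        if v.uniqueId in consumed:
            continue
        consumed.add(v.uniqueId)
        mate_key = None
        if b.mateId and b.mateId in by_id and b.mateId not in consumed:
            mate_key = b.mateId
        elif not b.mateId:
            for cand in by_coord.get((b.mateChrom, b.matePos, b.chrom, b.pos), []):
                if cand not in consumed:
                    mate_key = cand
                    break
        if b.mateId and mate_key is None and b.mateId not in by_id:
            log.warning("breakend %s: MATEID %s not found; single-ended",
                        v.uniqueId, b.mateId)
        if mate_key is not None:
            consumed.add(mate_key)
            mv, mb = by_id[mate_key]
            events.append(SVEvent(
                id=v.uniqueId, kind="BND",
                end1=(b.chrom, b.pos - 1), end2=(mb.chrom, mb.pos - 1),
                info=dict(v.info), sourceRow=(v, mv),
                joinSide1=b.joinSide, joinSide2=mb.joinSide,
            ))
        else:
            if not b.mateId:
                log.warning("breakend %s has no mate record; single-ended",
                            v.uniqueId)
            events.append(SVEvent(
                id=v.uniqueId, kind="BND",
                end1=(b.chrom, b.pos - 1), end2=None,
                info=dict(v.info), sourceRow=(v,),
                joinSide1=b.joinSide, joinSide2=None,
            ))
    return events


_SYMBOLIC = re.compile(r"^<(DEL|DUP|INV|TRA|BND|INS)(:[^>]+)?>$")


def sv_events(variants: Sequence[VariantFeature]) -> list[SVEvent]:
    """All SV events in a VCF: paired breakends plus symbolic records.

    Symbolic <DEL>/<DUP>/<INV>/<TRA> become two-ended events from POS and
    INFO END (CHR2 when present, Sniffles-style).
    """
    bnds = [v for v in variants if any(is_breakend_alt(a) for a in v.alts)]
    events = pair_mates(bnds)
    for v in variants:
        for alt in v.alts:
            m = _SYMBOLIC.match(alt)
            if m is None:
                continue
            kind = m.group(1)
            if kind in ("BND", "INS"):
                continue
            chr2 = v.info.get("CHR2", v.refName)
            end = v.info.get("END", v.end)
            events.append(SVEvent(
                id=v.uniqueId, kind=kind,
                end1=(v.refName, v.start),
                end2=(chr2, int(end) - 1),
                info=dict(v.info), sourceRow=(v,),
            ))
    return events


# ---------------------------------------------------------------------------
# BEDPE / STAR-fusion


def read_bedpe(path: str) -> list[SVEvent]:
    """BEDPE rows (>= 6 columns, 0-based half-open) to events at interval
    midpoints; extra columns retained in info."""
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"line {lineno}: BEDPE needs >= 6 columns")
            c1, s1, e1, c2, s2, e2 = cols[:6]
            mid1 = (int(s1) + int(e1)) // 2
            mid2 = (int(s2) + int(e2)) // 2
            info = {}
            if len(cols) > 6:
                info["name"] = cols[6]
            if len(cols) > 7:
                info["score"] = cols[7]
            if len(cols) > 9:
                info["strand1"], info["strand2"] = cols[8], cols[9]
            for i, extra in enumerate(cols[10:], 11):
                info[f"col{i}"] = extra
            events.append(SVEvent(
                id=info.get("name") or f"bedpe{lineno}", kind="BEDPE",
                end1=(c1, mid1), end2=(c2, mid2), info=info, sourceRow=lineno,
            ))
    return events


def read_starfusion(path: str) -> list[SVEvent]:
    """STAR-fusion default tsv: LeftBreakpoint/RightBreakpoint 'chr:pos:strand'."""
    events = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if header is None:
                header = [c.lstrip("#") for c in cols]
                for want in ("FusionName", "LeftBreakpoint", "RightBreakpoint"):
                    if want not in header:
                        raise FormatError(f"STAR-fusion header lacks {want}")
                continue
            row = dict(zip(header, cols))
            try:
                lc, lp, _ = row["LeftBreakpoint"].split(":")
                rc, rp, _ = row["RightBreakpoint"].split(":")
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad breakpoint string") from exc
            events.append(SVEvent(
                id=row["FusionName"], kind="fusion",
                end1=(lc, int(lp) - 1), end2=(rc, int(rp) - 1),
                info=row, sourceRow=lineno,
            ))
    return events


# ---------------------------------------------------------------------------
# table filtering


_CLAUSE = re.compile(r"^(?P<col>[A-Za-z_][\w.]*)(?P<op><=|>=|=|~|<|>)(?P<val>.*)$")


def filter_table(table, expression: str):
    """Filter a FeatureTable with whitespace-joined ANDed clauses.

    Clause forms: ``column=value`` (exact), ``column~value`` (substring),
    ``column<n``/``>``/``<=``/``>=`` (numeric), or a bare token matched as a
    substring against any text column.  Column names come from the table
    header (``info.*`` included).
    """
    from .table import FeatureTable

    expression = expression.strip()
    if not expression:
        return table
    header = table.header
    col_index = {name: i for i, name in enumerate(header)}
    predicates = []
    for clause in expression.split():
        m = _CLAUSE.match(clause)
        if m and m.group("col") in col_index:
            ci = col_index[m.group("col")]
            op, val = m.group("op"), m.group("val")
            if op in ("<", ">", "<=", ">="):
                try:
                    num = float(val)
                except ValueError:
                    raise FilterExpressionError(
                        f"clause {clause!r}: {val!r} is not a number"
                    )

                def num_pred(row, ci=ci, op=op, num=num):
                    v = row[ci]
                    if v is None:
                        return False
                    try:
                        v = float(v)
                    except (TypeError, ValueError):
                        return False
                    return {"<": v < num, ">": v > num,
                            "<=": v <= num, ">=": v >= num}[op]

                predicates.append(num_pred)
            elif op == "=":
                def eq_pred(row, ci=ci, val=val):
                    v = row[ci]
                    if v is None:
                        return False
                    if isinstance(v, (int, float)):
                        try:
                            return float(v) == float(val)
                        except ValueError:
                            return False
                    return str(v) == val

                predicates.append(eq_pred)
            else:  # '~'
                def sub_pred(row, ci=ci, val=val):
                    v = row[ci]
                    return v is not None and val in str(v)

                predicates.append(sub_pred)
        elif m and m.group("op") in ("=", "~", "<", ">", "<=", ">="):
            raise FilterExpressionError(
                f"unknown column {m.group('col')!r}; known: {header}"
            )
        else:
            token = clause

            def bare_pred(row, token=token):
                return any(
                    isinstance(v, str) and token in v for v in row
                )

            predicates.append(bare_pred)
    rows, prov = [], []
    for row, src in zip(table.rows, table.provenance):
        if all(p(row) for p in predicates):
            rows.append(row)
            prov.append(src)
    return FeatureTable(header=list(header), rows=rows, provenance=prov)


# ---------------------------------------------------------------------------
# breakpoint evidence


def breakpoint_panels(
    event: SVEvent, windowBp: int, assembly: Optional[Assembly] = None
) -> tuple[DisplayedRegions, Optional[DisplayedRegions]]:
    """One window per event end, centered and clamped to sequence bounds."""
    if windowBp <= 0:
        raise FormatError("windowBp must be positive")
    half = windowBp // 2

    def panel(end: tuple[str, int]) -> DisplayedRegions:
        refName, pos = end
        length = assembly.seq_length(refName) if assembly else None
        start = max(0, pos - half)
        stop = pos + half
        if length is not None:
            stop = min(stop, length)
            refName = assembly.canonical(refName)
        return DisplayedRegions([Region(refName, start, stop)])

    second = panel(event.end2) if event.end2 is not None else None
    if second is None:
        log.info("event %s is single-ended; second panel absent", event.id)
    return panel(event.end1), second


@dataclass(frozen=True)
class Connector:
    readName: str
    endA: tuple[int, str, int]  # (panel index, refName, refPos)
    endB: tuple[int, str, int]


def _panel_of(panels, refName: str, pos: int) -> Optional[int]:
    for i, displayed in enumerate(panels):
        if displayed is None:
            continue
        for region in displayed:
            if region.contains(refName, pos) or pos == region.end:
                return i
    return None


def gather_split_evidence(
    reads: Sequence, event: SVEvent,
    panels: Optional[Sequence[Optional[DisplayedRegions]]] = None,
    windowBp: int = 2000,
    assembly: Optional[Assembly] = None,
) -> list[Connector]:
    """Connectors between consecutive segments of split reads.

    Alignments are grouped by read name and ordered along the original read
    (via the clip-derived query span); each adjacent pair contributes one
    connector from the query-later reference edge of the earlier segment to
    the query-earlier edge of the later one.  Reads with one segment
    contribute nothing.
    """
    from .alignments import cigar_spans, query_span_on_read

    if panels is None:
        panels = breakpoint_panels(event, windowBp, assembly)
    groups: dict[str, list] = {}
    for read in reads:
        if read.is_secondary:
            continue
        groups.setdefault(read.name, []).append(read)
    connectors: list[Connector] = []
    for name in sorted(groups):
        segments = sorted(groups[name], key=lambda r: query_span_on_read(r)[0])
        for a, b in zip(segments, segments[1:]):
            a_span = cigar_spans(a.cigar)[0]
            b_span = cigar_spans(b.cigar)[0]
            # reference coordinate at the query-end edge of a / query-start of b
            a_pos = a.start if a.is_reverse else a.start + a_span
            b_pos = b.start + b_span if b.is_reverse else b.start
            pa = _panel_of(panels, a.refName, a_pos)
            pb = _panel_of(panels, b.refName, b_pos)
            if pa is None or pb is None:
                continue
            connectors.append(Connector(
                readName=name,
                endA=(pa, a.refName, a_pos),
                endB=(pb, b.refName, b_pos),
            ))
    return connectors
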