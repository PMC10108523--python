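"""Pairwise-synteny block model and parsers for PAF, MUMmer delta, UCSC
chain, and MCScan anchors, plus dotplot path geometry.

All query coordinates are stored on the forward query strand regardless of
the source convention: PAF already is; chain minus-strand coordinates are
converted with ``qSize - end, qSize - start``; delta reversed ranges flip
sign into the strand flag.  CIGAR ops follow the query-vs-target convention:
M advances both axes, I advances the query only, D/N advance the target only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import FormatError

log = logging.getLogger("genoscene.synteny")

_QUERY_OPS = set("MI=X")
_TARGET_OPS = set("MDN=X")


@dataclass
class SyntenyBlock:
    qName: str
    qLen: Optional[int]
    qStart: int
    qEnd: int
    strand: str  # '+' or '-'
    tName: str
    tLen: Optional[int]
    tStart: int
    tEnd: int
    score: Optional[float] = None
    cigar: Optional[list[tuple[str, int]]] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.qStart > self.qEnd or self.tStart > self.tEnd:
            raise FormatError(
                f"synteny block {self.qName}/{self.tName}: inverted span"
            )
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        if self.cigar is not None:
            t = sum(n for op, n in self.cigar if op in _TARGET_OPS)
            q = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if t != self.tEnd - self.tStart or q != self.qEnd - self.qStart:
                raise FormatError(
                    f"block {self.qName}/{self.tName}: CIGAR consumes "
                    f"({q},{t}) but spans are "
                    f"({self.qEnd - self.qStart},{self.tEnd - self.tStart})"
                )


def _merge_push(cigar: list[tuple[str, int]], op: str, n: int) -> None:
    if n <= 0:
        return
    if cigar and cigar[-1][0] == op:
        cigar[-1] = (op, cigar[-1][1] + n)
    else:
        cigar.append((op, n))


# ---------------------------------------------------------------------------
# PAF


def parse_paf(line: str, permissive: bool = False) -> SyntenyBlock:
    """One PAF line to a block; the cg:Z tag becomes the CIGAR.

    ``permissive`` accepts 10-column PAF-like rows (e.g. mashmap.out) by
    defaulting the residue/length/quality columns.
    """
    from .alignments import parse_cigar

    cols = line.rstrip("\n").split("\t")
    minimum = 10 if permissive else 12
    if len(cols) < minimum:
        raise FormatError(f"PAF line has {len(cols)} columns, expected >= {minimum}")
    cigar = None
    score = None
    for tag in cols[12:]:
        if tag.startswith("cg:Z:"):
            cigar = parse_cigar(tag[5:])
        elif tag.startswith("AS:i:"):
            score = float(tag[5:])
    if score is None and len(cols) > 9:
        try:
            score = float(cols[9])
        except ValueError:
            score = None
    return SyntenyBlock(
        qName=cols[0], qLen=int(cols[1]), qStart=int(cols[2]), qEnd=int(cols[3]),
        strand=cols[4], tName=cols[5], tLen=int(cols[6]),
        tStart=int(cols[7]), tEnd=int(cols[8]),
        score=score, cigar=cigar, source="paf",
    )


def read_paf(path: str, permissive: bool = False) -> list[SyntenyBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                blocks.append(parse_paf(line, permissive=permissive))
    return blocks


def write_paf(blocks: Iterable[SyntenyBlock], path: str) -> None:
    from .alignments import cigar_to_text

    with open(path, "w") as fh:
        for b in blocks:
            matches = b.cigar and sum(n for op, n in b.cigar if op in "M=")
            span = max(b.qEnd - b.qStart, b.tEnd - b.tStart)
            cols = [
                b.qName, str(b.qLen or 0), str(b.qStart), str(b.qEnd), b.strand,
                b.tName, str(b.tLen or 0), str(b.tStart), str(b.tEnd),
                str(matches or span), str(span), "60",
            ]
            if b.cigar is not None:
                cols.append("cg:Z:" + cigar_to_text(b.cigar))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# MUMmer delta


def parse_delta(text: str) -> list[SyntenyBlock]:
    """NUCMER .delta text to blocks.

    Alignment headers are ``rs re qs qe e1 e2 e3`` (1-based inclusive);
    ``qs > qe`` marks a reverse-strand alignment.  The signed indel-distance
    list is converted to a CIGAR: a distance d means |d|-1 matched positions
    then one gap — in the query for positive d (target-only base, D) and in
    the target for negative d (query-only base, I); the trailing run is
    matches.  Every list must end with the 0 terminator.
    """
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    i = 0
    # file header: paths line and program line (NUCMER/PROMER) when present
    if not lines[i].startswith(">"):
        i += 1
        if i < len(lines) and lines[i] in ("NUCMER", "PROMER"):
            i += 1
    blocks: list[SyntenyBlock] = []
    tname = qname = None
    tlen = qlen = None
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) != 4:
                raise FormatError(f"bad delta sequence header {line!r}")
            tname, qname = parts[0], parts[1]
            tlen, qlen = int(parts[2]), int(parts[3])
            i += 1
            continue
        header = line.split()
        if len(header) != 7:
            raise FormatError(f"bad delta alignment header {line!r}")
        rs, re_, qs, qe = (int(x) for x in header[:4])
        i += 1
        deltas = []
        terminated = False
        while i < len(lines):
            if lines[i].startswith(">"):
                break
            d = int(lines[i])
            i += 1
            if d == 0:
                terminated = True
                break
            deltas.append(d)
        if not terminated:
            raise FormatError(
                f"delta alignment {tname}/{qname} missing its 0 terminator"
            )
        t_start, t_end = rs - 1, re_
        if qs <= qe:
            strand, q_start, q_end = "+", qs - 1, qe
        else:
            strand, q_start, q_end = "-", qe - 1, qs
        cigar: list[tuple[str, int]] = []
        t_used = q_used = 0
        for d in deltas:
            run = abs(d) - 1
            _merge_push(cigar, "M", run)
            t_used += run
            q_used += run
            if d > 0:  # base in the target only: gap (deletion) in the query
                _merge_push(cigar, "D", 1)
                t_used += 1
            else:      # base in the query only
                _merge_push(cigar, "I", 1)
                q_used += 1
        t_rest = (t_end - t_start) - t_used
        q_rest = (q_end - q_start) - q_used
        if t_rest != q_rest or t_rest < 0:
            raise FormatError(
                f"delta alignment {tname}/{qname}: distances inconsistent "
                f"with spans (residual target {t_rest}, query {q_rest})"
            )
        _merge_push(cigar, "M", t_rest)
        blocks.append(SyntenyBlock(
            qName=qname, qLen=qlen, qStart=q_start, qEnd=q_end, strand=strand,
            tName=tname, tLen=tlen, tStart=t_start, tEnd=t_end,
            cigar=cigar, source="delta",
        ))
    return blocks


# ---------------------------------------------------------------------------
# UCSC chain


def parse_chain(text: str) -> list[SyntenyBlock]:
    """UCSC chain text to blocks.

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; then ``size dt dq`` triplets and a final bare
    size.  Minus-strand query coordinates are converted to forward-strand
    (qSize - end, qSize - start); triplets become M/D/I runs (dt advances the
    target, dq the query).
    """
    blocks: list[SyntenyBlock] = []
    lines = [ln.rstrip() for ln in text.splitlines()]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise FormatError(f"expected chain header, got {line!r}")
        parts = line.split()
        if len(parts) not in (12, 13):
            raise FormatError(f"chain header has {len(parts)} fields")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = parts[:12]
        if t_strand != "+":
            raise FormatError("chain target strand must be '+'")
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        cigar: list[tuple[str, int]] = []
        t_used = q_used = 0
        done = False
        while i < len(lines) and not done:
            row = lines[i].strip()
            i += 1
            if not row:
                continue
            fields = row.split()
            size = int(fields[0])
            _merge_push(cigar, "M", size)
            t_used += size
            q_used += size
            if len(fields) == 3:
                dt, dq = int(fields[1]), int(fields[2])
                _merge_push(cigar, "D", dt)
                _merge_push(cigar, "I", dq)
                t_used += dt
                q_used += dq
            elif len(fields) == 1:
                done = True
            else:
                raise FormatError(f"bad chain block line {row!r}")
        if t_used != t_end - t_start or q_used != q_end - q_start:
            raise FormatError(
                f"chain {t_name}/{q_name}: block sizes sum to ({t_used},{q_used}) "
                f"but spans are ({t_end - t_start},{q_end - q_start})"
            )
        if q_strand == "-":
            q_start, q_end = q_size - q_end, q_size - q_start
            strand = "-"
        else:
            strand = "+"
        blocks.append(SyntenyBlock(
            qName=q_name, qLen=q_size, qStart=q_start, qEnd=q_end, strand=strand,
            tName=t_name, tLen=t_size, tStart=t_start, tEnd=t_end,
            score=float(score), cigar=cigar, source="chain",
        ))
    return blocks


def write_chain(blocks: Iterable[SyntenyBlock], chain_id_start: int = 1) -> str:
    """Serialize blocks as chain text; parse_chain(write_chain(x)) == x.

    Minus-strand blocks are written with chain-native reverse-strand query
    coordinates (qSize - end, qSize - start), which parse_chain converts
    back to our forward-strand storage."""
    out = []
    for cid, b in enumerate(blocks, chain_id_start):
        if b.cigar is None:
            cigar = [("M", b.tEnd - b.tStart)]
        else:
            cigar = b.cigar
        out.append(" ".join(str(x) for x in [
            "chain", int(b.score or 0), b.tName, b.tLen or b.tEnd, "+",
            b.tStart, b.tEnd, b.qName, b.qLen or b.qEnd,
            b.strand, *(
                (b.qStart, b.qEnd) if b.strand == "+"
                else ((b.qLen or b.qEnd) - b.qEnd, (b.qLen or b.qEnd) - b.qStart)
            ),
            cid,
        ]))
        # collapse CIGAR into (size, dt, dq) triplets
        runs: list[list[int]] = []  # [size, dt, dq]
        current = [0, 0, 0]
        for op, n in cigar:
            if op in "M=X":
                if current[1] or current[2]:
                    runs.append(current)
                    current = [0, 0, 0]
                current[0] += n
            elif op in "DN":
                current[1] += n
            elif op == "I":
                current[2] += n
        runs.append(current)
        *body, last = runs
        for size, dt, dq in body:
            out.append(f"{size} {dt} {dq}")
        if last[1] or last[2]:
            # a trailing gap is not expressible in the bare final size line;
            # emit it as a triplet followed by a zero-size terminator
            out.append(f"{last[0]} {last[1]} {last[2]}")
            out.append("0")
        else:
            out.append(str(last[0]))
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# MCScan anchors


def _read_bed_genes(path: str) -> dict[str, tuple[str, int, int, str]]:
    genes = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"anchors BED needs >= 4 columns: {line!r}")
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            genes[cols[3]] = (cols[0], int(cols[1]), int(cols[2]), strand)
    return genes


def parse_anchors(
    anchorsPath: str, qBedPath: str, tBedPath: str
) -> list[SyntenyBlock]:
    """MCScan .anchors (+ two BEDs) to per-gene-pair blocks plus one merged
    block per '###' group (group strand by majority vote, ties '+')."""
    q_genes = _read_bed_genes(qBedPath)
    t_genes = _read_bed_genes(tBedPath)
    blocks: list[SyntenyBlock] = []
    group: list[SyntenyBlock] = []

    def close_group() -> None:
        if not group:
            return
        qn, tn = group[0].qName, group[0].tName
        members = [b for b in group if b.qName == qn and b.tName == tn]
        if len(members) != len(group):
            log.warning("anchors group spans multiple chromosome pairs; "
                        "merged block uses %s/%s", qn, tn)
        plus = sum(1 for b in members if b.strand == "+")
        blocks.append(SyntenyBlock(
            qName=qn, qLen=None,
            qStart=min(b.qStart for b in members),
            qEnd=max(b.qEnd for b in members),
            strand="+" if plus * 2 >= len(members) else "-",
            tName=tn, tLen=None,
            tStart=min(b.tStart for b in members),
            tEnd=max(b.tEnd for b in members),
            source="anchors-group",
        ))
        group.clear()

    with open(anchorsPath) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("###"):
                close_group()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"bad anchors line {line!r}")
            gq, gt = parts[0], parts[1]
            score = float(parts[2]) if len(parts) > 2 and parts[2] != "." else None
            if gq not in q_genes or gt not in t_genes:
                log.warning("anchors pair %s/%s missing from BED; skipped", gq, gt)
                continue
            qc, qs, qe, qstrand = q_genes[gq]
            tc, ts, te, tstrand = t_genes[gt]
            block = SyntenyBlock(
                qName=qc, qLen=None, qStart=qs, qEnd=qe,
                strand="+" if qstrand == tstrand else "-",
                tName=tc, tLen=None, tStart=ts, tEnd=te,
                score=score, source="anchors",
            )
            blocks.append(block)
            group.append(block)
    close_group()
    return blocks


# ---------------------------------------------------------------------------
# dotplot geometry


def dotplot_path(block: SyntenyBlock) -> list[tuple[int, int]]:
    """Polyline of (target bp, query bp) vertices for a block.

    Without a CIGAR: the two corners, anti-diagonal for '-'.  With a CIGAR:
    stepwise vertices — M advances both axes, D/N the target, I the query;
    on '-' the query coordinate steps downward from qEnd.  The target
    coordinate never decreases.
    """
    if block.cigar is None:
        if block.strand == "+":
            return [(block.tStart, block.qStart), (block.tEnd, block.qEnd)]
        return [(block.tStart, block.qEnd), (block.tEnd, block.qStart)]
    qdir = 1 if block.strand == "+" else -1
    q = block.qStart if block.strand == "+" else block.qEnd
    t = block.tStart
    vertices = [(t, q)]
    for op, n in block.cigar:
        if op in "M=X":
            t += n
            q += qdir * n
        elif op in "DN":
            t += n
        elif op == "I":
            q += qdir * n
        else:
            raise FormatError(f"unsupported CIGAR op {op!r} in synteny block")
        if vertices[-1] != (t, q):
            vertices.append((t, q))
    return vertices
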