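"""Synthetic-data generator: toy genomes, engineered structural variants,
split-aligned reads, and matching truth files.

Every generator is deterministic for a given seed (one `numpy` Generator per
call, draws in documented order).  Reads are error-free by default so that
evidence geometry is exact by construction: a read's alignment to the
reference is obtained by lifting its derived-genome interval through the SV
map rather than by running an aligner, which makes clip boundaries land
exactly on the simulated breakpoints.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignments import AlignedRead, cigar_to_text, revcomp
from .errors import FormatError
from .sv import LEFT_OF_POS, RIGHT_OF_POS, SVEvent
from .synteny import SyntenyBlock

log = logging.getLogger("genoscene.fixtures")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome


def make_genome(
    chromLengths: Sequence[int], seed: int, names: Optional[Sequence[str]] = None
) -> dict[str, str]:
    """Uniform-random A/C/G/T chromosomes, deterministic per seed."""
    if any(length < 1 for length in chromLengths):
        raise FormatError("chromosome lengths must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(names or (f"chr{i + 1}" for i in range(len(chromLengths))))
    genome = {}
    for name, length in zip(names, chromLengths):
        genome[name] = "".join(_BASES[rng.integers(0, 4, size=length)])
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    import pysam

    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    pysam.faidx(path)


# ---------------------------------------------------------------------------
# structural variants


@dataclass(frozen=True)
class SvSpec:
    """One engineered SV on the reference.

    deletion/duplication/inversion use (chrom, start, end); insertion uses
    (chrom, start, insSeq); translocation is reciprocal between cut points
    (chrom, start) and (chrom2, pos2) — both retained-left/retained-right
    pieces are rewired, yielding two junctions (two BND pairs).
    """

    kind: str
    chrom: str
    start: int
    end: Optional[int] = None
    insSeq: Optional[str] = None
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    id: str = ""


@dataclass(frozen=True)
class LiftSegment:
    dStart: int
    dEnd: int
    refChrom: Optional[str]  # None marks novel inserted sequence
    refStart: int
    strand: str  # '+' or '-'


@dataclass
class SvTruth:
    derived: dict[str, str]
    liftover: dict[str, list[LiftSegment]]
    vcf_text: str
    events: list[SVEvent]
    junctions: dict[str, tuple[tuple[str, int], tuple[str, int]]]
    ref_lengths: dict[str, int]


def _validate_specs(genome: dict[str, str], specs: Sequence[SvSpec]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for spec in specs:
        for chrom in filter(None, (spec.chrom, spec.chrom2)):
            if chrom not in genome:
                raise FormatError(f"SV {spec.id or spec.kind}: unknown chrom {chrom}")
        if spec.kind in ("deletion", "duplication", "inversion"):
            if spec.end is None or not (0 <= spec.start < spec.end <= len(genome[spec.chrom])):
                raise FormatError(f"SV {spec.id or spec.kind}: bad interval")
            by_chrom.setdefault(spec.chrom, []).append((spec.start, spec.end))
        elif spec.kind == "insertion":
            if not spec.insSeq or not (0 < spec.start < len(genome[spec.chrom])):
                raise FormatError(f"SV {spec.id or spec.kind}: bad insertion")
            by_chrom.setdefault(spec.chrom, []).append((spec.start, spec.start))
        elif spec.kind == "translocation":
            if spec.chrom2 is None or spec.pos2 is None:
                raise FormatError("translocation needs chrom2/pos2")
            if not (1 <= spec.start < len(genome[spec.chrom])) or not (
                1 <= spec.pos2 < len(genome[spec.chrom2])
            ):
                raise FormatError("translocation cut out of bounds")
        else:
            raise FormatError(f"unknown SV kind {spec.kind!r}")
    for chrom, intervals in by_chrom.items():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping SV intervals on {chrom}")


def _edited_piece(
    seq: str, chrom: str, lo: int, hi: int, specs: Sequence[SvSpec]
) -> list[tuple[Optional[str], int, int, str, str]]:
    """(refChrom, refLo, refHi, strand, text) segments realizing the intra-
    chromosomal SVs of ``specs`` inside reference window [lo, hi)."""
    local = sorted(
        (s for s in specs if s.chrom == chrom
         and s.kind in ("deletion", "duplication", "inversion", "insertion")
         and lo <= s.start and (s.end or s.start) <= hi),
        key=lambda s: s.start,
    )
    out = []
    cursor = lo
    for spec in local:
        if spec.start > cursor:
            out.append((chrom, cursor, spec.start, "+", seq[cursor:spec.start]))
        if spec.kind == "deletion":
            cursor = spec.end
        elif spec.kind == "duplication":
            out.append((chrom, spec.start, spec.end, "+", seq[spec.start:spec.end]))
            out.append((chrom, spec.start, spec.end, "+", seq[spec.start:spec.end]))
            cursor = spec.end
        elif spec.kind == "inversion":
            out.append((chrom, spec.start, spec.end, "-",
                        revcomp(seq[spec.start:spec.end])))
            cursor = spec.end
        else:  # insertion (the gap before spec.start was appended above)
            out.append((None, 0, len(spec.insSeq), "+", spec.insSeq))
            cursor = spec.start
    if cursor < hi:
        out.append((chrom, cursor, hi, "+", seq[cursor:hi]))
    return [o for o in out if o[2] > o[1] or o[0] is None]


def apply_svs(genome: dict[str, str], specs: Sequence[SvSpec]) -> SvTruth:
    """Realize the SVs, producing the derived genome, a truth VCF (BND pairs
    with mutual MATEIDs for translocation junctions, symbolic records
    otherwise), the derived->reference liftover map, and truth events."""
    _validate_specs(genome, specs)
    translocations = [s for s in specs if s.kind == "translocation"]
    cut_of: dict[str, SvSpec] = {}
    for t in translocations:
        for chrom in (t.chrom, t.chrom2):
            if chrom in cut_of:
                raise FormatError(f"chromosome {chrom} in two translocations")
        cut_of[t.chrom] = t
        cut_of[t.chrom2] = t

    derived: dict[str, str] = {}
    liftover: dict[str, list[LiftSegment]] = {}

    def assemble(name: str, pieces) -> None:
        segments: list[LiftSegment] = []
        chunks: list[str] = []
        pos = 0
        for ref_chrom, ref_lo, ref_hi, strand, text in pieces:
            segments.append(LiftSegment(pos, pos + len(text), ref_chrom,
                                        ref_lo, strand))
            chunks.append(text)
            pos += len(text)
        derived[name] = "".join(chunks)
        liftover[name] = segments

    handled: set[str] = set()
    for chrom, seq in genome.items():
        if chrom in handled:
            continue
        if chrom in cut_of:
            t = cut_of[chrom]
            a, b = t.chrom, t.chrom2
            ca, cb = t.start, t.pos2
            seq_a, seq_b = genome[a], genome[b]
            assemble(a, _edited_piece(seq_a, a, 0, ca, specs)
                     + _edited_piece(seq_b, b, cb, len(seq_b), specs))
            assemble(b, _edited_piece(seq_b, b, 0, cb, specs)
                     + _edited_piece(seq_a, a, ca, len(seq_a), specs))
            handled.update((a, b))
        else:
            assemble(chrom, _edited_piece(seq, chrom, 0, len(seq), specs))
            handled.add(chrom)

    # --- truth VCF + events
    records: list[tuple[str, int, str]] = []  # (chrom, pos, body) for sorting
    events: list[SVEvent] = []
    junctions: dict[str, tuple[tuple[str, int], tuple[str, int]]] = {}
    counter = 0
    for spec in specs:
        counter += 1
        sid = spec.id or f"sv{counter}"
        seq = genome[spec.chrom]
        if spec.kind in ("deletion", "duplication", "inversion"):
            svtype = {"deletion": "DEL", "duplication": "DUP",
                      "inversion": "INV"}[spec.kind]
            pos = spec.start  # 1-based anchor base before the interval
            ref_base = seq[pos - 1] if pos >= 1 else "N"
            info = f"SVTYPE={svtype};END={spec.end}"
            records.append((spec.chrom, pos,
                            f"{spec.chrom}\t{pos}\t{sid}\t{ref_base}\t<{svtype}>"
                            f"\t60\tPASS\t{info}"))
            events.append(SVEvent(id=sid, kind=svtype,
                                  end1=(spec.chrom, pos - 1),
                                  end2=(spec.chrom, spec.end - 1)))
        elif spec.kind == "insertion":
            pos = spec.start
            ref_base = seq[pos - 1]
            info = f"SVTYPE=INS;SVLEN={len(spec.insSeq)}"
            records.append((spec.chrom, pos,
                            f"{spec.chrom}\t{pos}\t{sid}\t{ref_base}\t<INS>"
                            f"\t60\tPASS\t{info}"))
        else:  # reciprocal translocation: two junctions, four BND records
            a, b = spec.chrom, spec.chrom2
            ca, cb = spec.start, spec.pos2
            seq_a, seq_b = genome[a], genome[b]
            pairs = [
                # junction 1: left of ca joined to right of cb
                (f"{sid}_j1a", a, ca, seq_a[ca - 1],
                 f"{seq_a[ca - 1]}[{b}:{cb + 1}[", f"{sid}_j1b"),
                (f"{sid}_j1b", b, cb + 1, seq_b[cb],
                 f"]{a}:{ca}]{seq_b[cb]}", f"{sid}_j1a"),
                # junction 2: left of cb joined to right of ca
                (f"{sid}_j2a", b, cb, seq_b[cb - 1],
                 f"{seq_b[cb - 1]}[{a}:{ca + 1}[", f"{sid}_j2b"),
                (f"{sid}_j2b", a, ca + 1, seq_a[ca],
                 f"]{b}:{cb}]{seq_a[ca]}", f"{sid}_j2a"),
            ]
            for rid, chrom, pos, ref_base, alt, mate in pairs:
                records.append((chrom, pos,
                                f"{chrom}\t{pos}\t{rid}\t{ref_base}\t{alt}"
                                f"\t60\tPASS\tSVTYPE=BND;MATEID={mate}"))
            events.append(SVEvent(id=f"{sid}_j1a", kind="BND",
                                  end1=(a, ca - 1), end2=(b, cb),
                                  joinSide1=LEFT_OF_POS, joinSide2=RIGHT_OF_POS))
            events.append(SVEvent(id=f"{sid}_j2a", kind="BND",
                                  end1=(b, cb - 1), end2=(a, ca),
                                  joinSide1=LEFT_OF_POS, joinSide2=RIGHT_OF_POS))
            junctions[f"{sid}_j1"] = ((a, ca), (b, cb))
            junctions[f"{sid}_j2"] = ((b, cb), (a, ca))

    header = ["##fileformat=VCFv4.2"]
    for chrom, seq in genome.items():
        header.append(f"##contig=<ID={chrom},length={len(seq)}>")
    header += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    order = {c: i for i, c in enumerate(genome)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    vcf_text = "\n".join(header + [r[2] for r in records]) + "\n"
    return SvTruth(
        derived=derived, liftover=liftover, vcf_text=vcf_text, events=events,
        junctions=junctions,
        ref_lengths={c: len(s) for c, s in genome.items()},
    )


# ---------------------------------------------------------------------------
# read simulation


def _pieces_for_read(
    segments: Sequence[LiftSegment], pos: int, length: int
) -> list[tuple[int, int, Optional[str], int, int, str]]:
    """(readOff0, readOff1, refChrom, refLo, refHi, strand) per overlapped
    liftover segment, in read order."""
    pieces = []
    for seg in segments:
        lo = max(pos, seg.dStart)
        hi = min(pos + length, seg.dEnd)
        if lo >= hi:
            continue
        if seg.refChrom is None:
            pieces.append((lo - pos, hi - pos, None, 0, 0, "+"))
        elif seg.strand == "+":
            ref_lo = seg.refStart + (lo - seg.dStart)
            pieces.append((lo - pos, hi - pos, seg.refChrom,
                           ref_lo, ref_lo + (hi - lo), "+"))
        else:
            ref_hi = seg.refStart + (seg.dEnd - lo)
            pieces.append((lo - pos, hi - pos, seg.refChrom,
                           ref_hi - (hi - lo), ref_hi, "-"))
    return pieces


def _runs_from_pieces(pieces) -> list[dict]:
    """Merge colinear pieces into alignment runs with read-order op lists."""
    runs: list[dict] = []
    current: Optional[dict] = None
    pending_ins = 0
    for piece in pieces:
        q0, q1, chrom, ref_lo, ref_hi, strand = piece
        if chrom is None:
            pending_ins += q1 - q0
            continue
        if current is not None and chrom == current["chrom"] and strand == current["strand"]:
            gap = (ref_lo - current["refHi"] if strand == "+"
                   else current["refLo"] - ref_hi)
            contiguous_q = q0 - pending_ins == current["q1"]
            if gap >= 0 and contiguous_q:
                if pending_ins:
                    current["ops"].append(("I", pending_ins))
                if gap:
                    current["ops"].append(("D", gap))
                current["ops"].append(("M", q1 - q0))
                current["q1"] = q1
                current["refLo"] = min(current["refLo"], ref_lo)
                current["refHi"] = max(current["refHi"], ref_hi)
                pending_ins = 0
                continue
        if current is not None:
            runs.append(current)
        pending_ins = 0
        current = {"q0": q0, "q1": q1, "chrom": chrom, "strand": strand,
                   "refLo": ref_lo, "refHi": ref_hi, "ops": [("M", q1 - q0)]}
    if current is not None:
        runs.append(current)
    return runs


def _mm_for_read(original: str, rng) -> Optional[tuple[str, list[int]]]:
    """Mark a random subset of C bases as 5mC; deltas computed directly on
    the original-read C ranks (independent of the tag decoder's walk)."""
    c_positions = [i for i, b in enumerate(original) if b == "C"]
    if not c_positions:
        return None
    chosen = [i for i in range(len(c_positions)) if rng.random() < 0.5]
    if not chosen:
        chosen = [0]
    deltas = []
    prev = -1
    for rank in chosen:
        deltas.append(rank - prev - 1)
        prev = rank
    mm = "C+m," + ",".join(str(d) for d in deltas) + ";"
    ml = [int(rng.integers(0, 256)) for _ in chosen]
    return mm, ml


def simulate_reads(
    truth: SvTruth,
    readLenBp: int = 2000,
    coverage: float = 10.0,
    seed: int = 0,
    mm_fraction: float = 0.0,
) -> tuple[list[AlignedRead], dict[str, list[str]]]:
    """Error-free reads sampled uniformly from the derived genome, aligned to
    the reference by lifting through the SV map.

    A read crossing an SV junction becomes >= 2 alignment records (primary +
    supplementary with mutual SA tags and exact soft-clip boundaries).
    Returns the records plus, per truth junction id, the names of reads whose
    split spans that junction.
    """
    if coverage <= 0:
        raise FormatError("coverage must be positive")
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    junction_reads: dict[str, list[str]] = {j: [] for j in truth.junctions}
    coord_to_junction = {coords: jid for jid, coords in truth.junctions.items()}
    for chrom in truth.derived:
        seq = truth.derived[chrom]
        if len(seq) < readLenBp:
            continue
        n_reads = int(round(coverage * len(seq) / readLenBp))
        starts = rng.integers(0, len(seq) - readLenBp + 1, size=n_reads)
        for i, pos in enumerate(sorted(int(p) for p in starts)):
            name = f"read_{chrom}_{i:05d}"
            read_seq = seq[pos:pos + readLenBp]
            pieces = _pieces_for_read(truth.liftover[chrom], pos, readLenBp)
            runs = _runs_from_pieces(pieces)
            if not runs:
                continue
            primary = max(range(len(runs)),
                          key=lambda k: runs[k]["q1"] - runs[k]["q0"])
            records = []
            for k, run in enumerate(runs):
                if run["strand"] == "+":
                    ops = list(run["ops"])
                    pre, post = run["q0"], readLenBp - run["q1"]
                    stored = read_seq
                else:
                    ops = list(reversed(run["ops"]))
                    pre, post = readLenBp - run["q1"], run["q0"]
                    stored = revcomp(read_seq)
                cigar = ([("S", pre)] if pre else []) + ops + \
                        ([("S", post)] if post else [])
                flags = (16 if run["strand"] == "-" else 0) | \
                        (0 if k == primary else 0x800)
                records.append(AlignedRead(
                    name=name, refName=run["chrom"], start=run["refLo"],
                    cigar=cigar, strand=run["strand"], flags=flags,
                    mapq=60, seq=stored, tags={"NM": 0},
                ))
            if len(records) > 1:
                for k, rec in enumerate(records):
                    others = [
                        f"{r.refName},{r.start + 1},{r.strand},"
                        f"{cigar_to_text(r.cigar)},{r.mapq},0"
                        for j2, r in enumerate(records) if j2 != k
                    ]
                    rec.tags["SA"] = ";".join(others) + ";"
                for r1, r2 in zip(runs, runs[1:]):
                    end1 = ((r1["chrom"],
                             r1["refHi"] if r1["strand"] == "+" else r1["refLo"]))
                    end2 = ((r2["chrom"],
                             r2["refLo"] if r2["strand"] == "+" else r2["refHi"]))
                    jid = coord_to_junction.get((end1, end2)) or \
                        coord_to_junction.get((end2, end1))
                    if jid is not None:
                        junction_reads[jid].append(name)
            if mm_fraction and len(records) == 1 and rng.random() < mm_fraction:
                mm = _mm_for_read(read_seq, rng)
                if mm is not None:
                    records[0].tags["MM"] = mm[0]
                    records[0].tags["ML"] = mm[1]
            reads.extend(records)
    return reads, junction_reads


def simulate_modified_reads(
    n: int, readLenBp: int = 120, seed: int = 0, refName: str = "chr1"
) -> list[AlignedRead]:
    """Standalone reads carrying MM/ML tags, alternating strand, for
    modification-decoding round trips."""
    rng = np.random.default_rng(seed)
    reads = []
    made = 0
    while made < n:
        original = "".join(_BASES[rng.integers(0, 4, size=readLenBp)])
        mm = _mm_for_read(original, rng)
        if mm is None:
            continue
        reverse = made % 2 == 1
        stored = revcomp(original) if reverse else original
        reads.append(AlignedRead(
            name=f"modread_{made:04d}", refName=refName,
            start=int(rng.integers(0, 10_000)),
            cigar=[("M", readLenBp)],
            strand="-" if reverse else "+",
            flags=16 if reverse else 0,
            seq=stored, tags={"MM": mm[0], "ML": mm[1]},
        ))
        made += 1
    return reads


# ---------------------------------------------------------------------------
# synteny simulation


def simulate_synteny(truth: SvTruth) -> list[SyntenyBlock]:
    """One PAF-style block per contiguous lifted segment of the derived
    genome; strands reflect inversions; CIGARs are full-length matches."""
    blocks = []
    for chrom, segments in truth.liftover.items():
        qlen = len(truth.derived[chrom])
        for seg in segments:
            if seg.refChrom is None:
                continue
            length = seg.dEnd - seg.dStart
            blocks.append(SyntenyBlock(
                qName=chrom, qLen=qlen, qStart=seg.dStart, qEnd=seg.dEnd,
                strand=seg.strand, tName=seg.refChrom,
                tLen=truth.ref_lengths[seg.refChrom],
                tStart=seg.refStart, tEnd=seg.refStart + length,
                cigar=[("M", length)], source="simulated",
            ))
    return blocks


# ---------------------------------------------------------------------------
# annotation + serialization helpers


def make_genes(
    genome: dict[str, str], n_per_chrom: int, seed: int, geneLenBp: int = 900
):
    """Random non-overlapping gene -> mRNA -> exon features with stable names."""
    from .features import Feature

    rng = np.random.default_rng(seed)
    feats = []
    counter = 0
    for chrom, seq in genome.items():
        slots = max(1, (len(seq) - geneLenBp) // max(n_per_chrom, 1))
        for i in range(n_per_chrom):
            start = i * slots + int(rng.integers(0, max(1, slots - geneLenBp)))
            end = min(start + geneLenBp, len(seq))
            if end <= start:
                continue
            counter += 1
            name = f"GENE{counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            gene = Feature(f"gene{counter:04d}", chrom, start, end, strand,
                           "gene", name,
                           {"description": [f"synthetic locus {name}"]})
            mrna = Feature(f"mrna{counter:04d}", chrom, start, end, strand,
                           "mRNA", f"{name}.1")
            exon_end = start + max((end - start) // 2, 1)
            mrna.subfeatures.append(
                Feature(f"exon{counter:04d}", chrom, start, exon_end,
                        strand, "exon"))
            gene.subfeatures.append(mrna)
            feats.append(gene)
    return feats


def write_sam(reads: Sequence[AlignedRead], ref_lengths: dict[str, int],
              path: str) -> None:
    order = {c: i for i, c in enumerate(ref_lengths)}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for read in sorted(reads, key=lambda r: (order[r.refName], r.start,
                                                 r.name, r.flags)):
            tags = []
            for key in sorted(read.tags):
                value = read.tags[key]
                if key in ("NM",):
                    tags.append(f"{key}:i:{value}")
                elif key == "ML":
                    tags.append("ML:B:C," + ",".join(str(v) for v in value))
                elif isinstance(value, int):
                    tags.append(f"{key}:i:{value}")
                else:
                    tags.append(f"{key}:Z:{value}")
            fh.write("\t".join([
                read.name, str(read.flags), read.refName, str(read.start + 1),
                str(read.mapq), cigar_to_text(read.cigar), "*", "0", "0",
                read.seq or "*", "*",
            ] + tags) + "\n")


def write_coverage_bigwig(reads: Sequence[AlignedRead],
                          ref_lengths: dict[str, int], path: str) -> None:
    """Per-base read-depth BigWig over the whole reference."""
    import pyBigWig

    from .alignments import compute_coverage
    from .genome import Region

    bw = pyBigWig.open(path, "w")
    bw.addHeader(list(ref_lengths.items()))
    for chrom, length in ref_lengths.items():
        signal = compute_coverage(
            [r for r in reads if r.refName == chrom], Region(chrom, 0, length))
        values = np.array([v if v is not None else 0.0 for v in signal.values])
        bw.addEntries(chrom, 0, values=values, span=1, step=1)
    bw.close()


# ---------------------------------------------------------------------------
# presets


def default_sv_demo_specs() -> list[SvSpec]:
    """The desk-scale SV story: a reciprocal translocation (two junction
    events), an inversion, and a deletion on a 2 x 100 kb genome."""
    return [
        SvSpec(kind="translocation", chrom="chr1", start=30_000,
               chrom2="chr2", pos2=40_000, id="tra1"),
        SvSpec(kind="inversion", chrom="chr1", start=60_000, end=70_000,
               id="inv1"),
        SvSpec(kind="deletion", chrom="chr2", start=70_000, end=70_500,
               id="del1"),
    ]


def make_preset(preset: str, seed: int, outdir: str) -> dict:
    """Write a complete offline fixture bundle; returns a manifest dict.

    Presets: ``sv-demo`` (2 x 100 kb genome + SV story above, long reads,
    truth VCF/PAF/GFF3/BEDPE and a ready-to-render config.json) and ``tiny``
    (2 x 5 kb, no SVs).
    """
    os.makedirs(outdir, exist_ok=True)
    if preset == "sv-demo":
        lengths, specs = [100_000, 100_000], default_sv_demo_specs()
        read_len, coverage = 2000, 10.0
    elif preset == "tiny":
        lengths, specs = [5000, 5000], []
        read_len, coverage = 500, 5.0
    else:
        raise FormatError(f"unknown preset {preset!r}")
    genome = make_genome(lengths, seed)
    truth = apply_svs(genome, specs)
    reads, junction_reads = simulate_reads(
        truth, readLenBp=read_len, coverage=coverage, seed=seed + 1,
        mm_fraction=0.2)
    blocks = simulate_synteny(truth)
    genes = make_genes(genome, 20, seed + 2)

    from .features import write_gff3
    from .synteny import write_paf

    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "derived": os.path.join(outdir, "derived.fa"),
        "reads": os.path.join(outdir, "reads.sam"),
        "truth_vcf": os.path.join(outdir, "truth.vcf"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "synteny": os.path.join(outdir, "alignment.paf"),
        "config": os.path.join(outdir, "config.json"),
        "truth_json": os.path.join(outdir, "truth.json"),
    }
    write_fasta(genome, paths["reference"])
    write_fasta(truth.derived, paths["derived"])
    write_sam(reads, truth.ref_lengths, paths["reads"])
    with open(paths["truth_vcf"], "w") as fh:
        fh.write(truth.vcf_text)
    write_gff3(genes, paths["genes"])
    write_paf(blocks, paths["synteny"])
    config = {
        "formatVersion": 1,
        "assemblies": [
            {"name": "ref", "fasta": paths["reference"]},
            {"name": "derived", "fasta": paths["derived"]},
        ],
        "tracks": [
            {"trackId": "genes", "type": "feature", "assemblyNames": ["ref"],
             "path": paths["genes"]},
            {"trackId": "reads", "type": "alignments", "assemblyNames": ["ref"],
             "path": paths["reads"]},
            {"trackId": "svs", "type": "variant", "assemblyNames": ["ref"],
             "path": paths["truth_vcf"]},
            {"trackId": "synteny", "type": "synteny",
             "assemblyNames": ["ref", "derived"], "path": paths["synteny"]},
        ],
    }
    with open(paths["config"], "w") as fh:
        json.dump(config, fh, indent=2)
    manifest = {
        "preset": preset,
        "seed": seed,
        "paths": paths,
        "events": [
            {"id": e.id, "kind": e.kind, "end1": list(e.end1),
             "end2": list(e.end2) if e.end2 else None,
             "joinSide1": e.joinSide1, "joinSide2": e.joinSide2}
            for e in truth.events
        ],
        "junction_reads": junction_reads,
    }
    with open(paths["truth_json"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
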