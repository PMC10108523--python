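"""The alignments-track brain: pileup layout, coverage, CIGAR arithmetic,
soft-clip/insertion markers, MM/ML base-modification decoding, read policies,
and read-vs-reference path extraction.

Reads are modelled by :class:`AlignedRead`, a thin value object convertible
from pysam records so BAM/CRAM/SAM all flow through the same code.  SAM
conventions apply throughout: the stored SEQ of a reverse-strand alignment is
the reverse complement of the original read, H/S clips count toward the
original read length, and D/N consume reference without adding depth.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import FormatError, PolicyError, TagError
from .features import QuantSignal, n_bins
from .genome import Region

log = logging.getLogger("genoscene.alignments")

CIGAR_OPS = "MIDNSHP=X"
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_DEPTH_OPS = set("M=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text in ("*", ""):
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise FormatError(f"malformed CIGAR {text!r}")
    return ops


def cigar_to_text(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) or "*"


@dataclass
class AlignedRead:
    name: str
    refName: str
    start: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    strand: str = "+"
    flags: int = 0
    mapq: int = 60
    seq: Optional[str] = None
    quals: Optional[Sequence[int]] = None
    tags: dict = field(default_factory=dict)
    mate: Optional[tuple[str, int, bool]] = None  # (refName, pos, is_reverse)

    def __post_init__(self) -> None:
        if self.seq is not None and self.cigar:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if qlen != len(self.seq):
                raise FormatError(
                    f"read {self.name}: CIGAR consumes {qlen} query bases "
                    f"but SEQ has {len(self.seq)}"
                )

    @property
    def uniqueId(self) -> str:
        return f"{self.name}/{self.refName}:{self.start}:{self.flags}"

    @property
    def is_reverse(self) -> bool:
        return self.strand == "-"

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & 0x800)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & 0x100)

    @property
    def ref_end(self) -> int:
        return self.start + cigar_spans(self.cigar)[0]

    @classmethod
    def from_pysam(cls, aln) -> "AlignedRead":
        cigar = parse_cigar(aln.cigarstring or "*")
        tags = dict(aln.get_tags())
        mate = None
        if aln.is_paired and aln.next_reference_name is not None:
            mate = (aln.next_reference_name, aln.next_reference_start,
                    aln.mate_is_reverse)
        return cls(
            name=aln.query_name,
            refName=aln.reference_name,
            start=aln.reference_start,
            cigar=cigar,
            strand="-" if aln.is_reverse else "+",
            flags=aln.flag,
            mapq=aln.mapping_quality,
            seq=aln.query_sequence,
            quals=list(aln.query_qualities) if aln.query_qualities is not None else None,
            tags=tags,
            mate=mate,
        )


def read_alignments(path: str, region: Optional[Region] = None,
                    reference: Optional[str] = None) -> list[AlignedRead]:
    """Load SAM/BAM/CRAM records (CRAM needs an explicit reference FASTA)."""
    import pysam

    kwargs = {}
    if reference is not None:
        kwargs["reference_filename"] = reference
    save = pysam.set_verbosity(0)  # silence index warnings on SAM text
    try:
        with pysam.AlignmentFile(path, **kwargs) as fh:
            if region is not None and fh.has_index():
                it = fh.fetch(region.refName, region.start, region.end)
                return [AlignedRead.from_pysam(a) for a in it if not a.is_unmapped]
            reads = [AlignedRead.from_pysam(a) for a in fh if not a.is_unmapped]
    finally:
        pysam.set_verbosity(save)
    if region is not None:
        reads = [
            r for r in reads
            if r.refName == region.refName
            and r.start < region.end and r.ref_end > region.start
        ]
    return reads


# ---------------------------------------------------------------------------
# CIGAR arithmetic


def cigar_spans(cigar: Sequence[tuple[str, int]]) -> tuple[int, int, int, int]:
    """(refSpan, querySpan incl. soft clips, clippedPrefix, clippedSuffix).

    Clip lengths count both H and S; querySpan counts S but not H, per SAM
    consumption rules.
    """
    ref = query = 0
    for op, n in cigar:
        if op not in CIGAR_OPS:
            raise FormatError(f"unknown CIGAR op {op!r}")
        if op in _REF_OPS:
            ref += n
        if op in _QUERY_OPS:
            query += n
    prefix = suffix = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in "HS":
        prefix += cigar[i][1]
        i += 1
    j = len(cigar) - 1
    while j > i and cigar[j][0] in "HS":
        suffix += cigar[j][1]
        j -= 1
    return ref, query, prefix, suffix


def full_read_length(read: AlignedRead) -> int:
    """Original read length including hard-clipped bases."""
    hard = sum(n for op, n in read.cigar if op == "H")
    soft_query = sum(n for op, n in read.cigar if op in _QUERY_OPS)
    return soft_query + hard


def query_span_on_read(read: AlignedRead) -> tuple[int, int]:
    """Aligned interval on the original full-length read (clips removed).

    For a reverse-strand alignment the stored clips are mirrored back onto
    the original read orientation.
    """
    _, _, prefix, suffix = cigar_spans(read.cigar)
    length = full_read_length(read)
    if read.is_reverse:
        return suffix, length - prefix
    return prefix, length - suffix


def find_softclip_markers(read: AlignedRead) -> list[tuple[int, int, str]]:
    """(refPos, clipLen, side) for each soft clip, anchored at alignment edges."""
    out = []
    cigar = [c for c in read.cigar if c[0] != "H"]
    if cigar and cigar[0][0] == "S":
        out.append((read.start, cigar[0][1], "left"))
    if len(cigar) > 1 and cigar[-1][0] == "S":
        ref_span = cigar_spans(read.cigar)[0]
        out.append((read.start + ref_span, cigar[-1][1], "right"))
    return out


def find_insertions(read: AlignedRead, minLenBp: int = 1) -> list[tuple[int, int]]:
    """(refPos, insLen) per I op of at least ``minLenBp``."""
    out = []
    rpos = read.start
    for op, n in read.cigar:
        if op == "I" and n >= minLenBp:
            out.append((rpos, n))
        if op in _REF_OPS:
            rpos += n
    return out


def read_to_ref_path(read: AlignedRead) -> list[tuple[int, int, int, int, str]]:
    """Segments (qStart, qEnd, rStart, rEnd, kind) over the stored sequence.

    match segments advance both axes, ins advances query only, del advances
    reference only; concatenated they consume exactly the aligned spans.
    """
    segments = []
    qpos = read.cigar[0][1] if read.cigar and read.cigar[0][0] == "S" else 0
    rpos = read.start
    for op, n in read.cigar:
        if op in "M=X":
            segments.append((qpos, qpos + n, rpos, rpos + n, "match"))
            qpos += n
            rpos += n
        elif op == "I":
            segments.append((qpos, qpos + n, rpos, rpos, "ins"))
            qpos += n
        elif op in "DN":
            segments.append((qpos, qpos, rpos, rpos + n, "del"))
            rpos += n
    return segments


def base_at(read: AlignedRead, refPos: int) -> Optional[str]:
    """Observed base at a reference position: A/C/G/T, 'del', or None."""
    if read.seq is None:
        return None
    qpos = read.cigar[0][1] if read.cigar and read.cigar[0][0] == "S" else 0
    rpos = read.start
    for op, n in read.cigar:
        if op in "M=X":
            if rpos <= refPos < rpos + n:
                return read.seq[qpos + (refPos - rpos)].upper()
            qpos += n
            rpos += n
        elif op == "I":
            qpos += n
        elif op in "DN":
            if rpos <= refPos < rpos + n:
                return "del"
            rpos += n
    return None


# ---------------------------------------------------------------------------
# pileup layout


@dataclass
class PileupLayout:
    rowOf: dict[str, int]
    rowCount: int
    paddingBp: int = 0


def assign_rows(
    intervals: Sequence[tuple], paddingBp: int = 0
) -> PileupLayout:
    """Greedy first-fit row assignment for pre-sorted intervals.

    ``intervals`` items are ``(uniqueId, startBp, endBp)`` (or bare
    ``(startBp, endBp)``, keyed by index), sorted ascending by start with
    ties broken by longer-first then uniqueId.  Each interval takes the
    lowest row whose last occupied end + paddingBp <= start; this left-
    endpoint greedy colors interval graphs optimally, so rowCount equals the
    maximum overlap depth of the padded intervals.
    """
    items = []
    for i, item in enumerate(intervals):
        if len(item) == 2:
            uid, start, end = str(i), item[0], item[1]
        else:
            uid, start, end = item
        items.append((uid, int(start), int(end)))
    for a, b in zip(items, items[1:]):
        if (a[1], -(a[2] - a[1]), a[0]) > (b[1], -(b[2] - b[1]), b[0]):
            raise FormatError(
                "assign_rows requires intervals sorted by start "
                "(ties: longer first, then uniqueId)"
            )
    row_ends: list[int] = []
    row_of: dict[str, int] = {}
    for uid, start, end in items:
        for row, last_end in enumerate(row_ends):
            if last_end + paddingBp <= start:
                row_ends[row] = end
                row_of[uid] = row
                break
        else:
            row_of[uid] = len(row_ends)
            row_ends.append(end)
    return PileupLayout(rowOf=row_of, rowCount=len(row_ends), paddingBp=paddingBp)


def layout_reads(reads: Sequence[AlignedRead], paddingBp: int = 2) -> PileupLayout:
    """assign_rows over reads, extending intervals by their soft clips so
    clipped reads do not visually collide."""
    intervals = []
    for r in reads:
        ref_span, _, prefix, suffix = cigar_spans(r.cigar)
        intervals.append((r.uniqueId, r.start - prefix, r.start + ref_span + suffix))
    intervals.sort(key=lambda t: (t[1], -(t[2] - t[1]), t[0]))
    return assign_rows(intervals, paddingBp)


def compute_coverage(
    reads: Iterable[AlignedRead], region: Region, binSizeBp: int = 1
) -> QuantSignal:
    """Per-bin mean read depth; deletions/introns (D/N) do not add depth."""
    depth = np.zeros(region.length, dtype=np.int64)
    for read in reads:
        if read.refName != region.refName:
            continue
        rpos = read.start
        for op, n in read.cigar:
            if op in _DEPTH_OPS:
                lo = max(rpos, region.start)
                hi = min(rpos + n, region.end)
                if lo < hi:
                    depth[lo - region.start:hi - region.start] += 1
            if op in _REF_OPS:
                rpos += n
    values = []
    for b in range(n_bins(region.length, binSizeBp)):
        chunk = depth[b * binSizeBp:(b + 1) * binSizeBp]
        values.append(float(chunk.mean()))
    return QuantSignal(region, binSizeBp, values)


# ---------------------------------------------------------------------------
# MM/ML base modifications


@dataclass(frozen=True)
class ModificationCall:
    readPos: int  # 0-based on the stored (SEQ) sequence
    canonicalBase: str  # base on the original read (e.g. 'C' for 5mC)
    modCode: str  # e.g. 'm', 'h', or a numeric ChEBI code
    likelihood: Optional[float] = None
    mode: str = ""  # trailing '.'/'?' flag of the MM group, kept for re-encoding


_MM_GROUP = re.compile(r"^([ACGTUN])([-+])([a-zA-Z]+|\d+)([.?]?)$")


def _occurrence_positions(read: AlignedRead, base: str) -> list[int]:
    """Stored-sequence indices of ``base`` occurrences in original-read order.

    For reverse-strand alignments the original read is the reverse
    complement of SEQ, so occurrences are walked from the stored 3' end on
    the complemented base.
    """
    seq = read.seq.upper()
    if not read.is_reverse:
        if base == "N":
            return list(range(len(seq)))
        return [i for i, b in enumerate(seq) if b == base]
    comp = base.translate(_COMPLEMENT)
    if base == "N":
        return list(range(len(seq) - 1, -1, -1))
    return [j for j in range(len(seq) - 1, -1, -1) if seq[j] == comp]


def decode_modifications(read: AlignedRead) -> list[ModificationCall]:
    """Decode the MM (and optional ML) tags into per-base calls.

    The MM delta encoding is walked per the SAM tags specification: within
    each ``base+code,counts`` group, skip ``count`` occurrences of the base
    (counted along the original read), then mark the next.  ML bytes map to
    likelihood ``(v + 0.5) / 256``.
    """
    mm = read.tags.get("MM") or read.tags.get("Mm")
    if mm is None:
        raise TagError(f"read {read.name}: no MM tag")
    if read.seq is None:
        raise TagError(f"read {read.name}: MM decoding requires SEQ")
    ml = read.tags.get("ML") or read.tags.get("Ml")
    ml = list(ml) if ml is not None else None
    calls: list[ModificationCall] = []
    ml_index = 0
    for group in mm.rstrip(";").split(";"):
        if not group:
            continue
        head, *deltas = group.split(",")
        m = _MM_GROUP.match(head)
        if m is None:
            raise TagError(f"read {read.name}: malformed MM group {group!r}")
        base, strand_char, code, mode = m.groups()
        if strand_char != "+":
            raise TagError(
                f"read {read.name}: MM strand {strand_char!r} unsupported"
            )
        occurrences = _occurrence_positions(read, base)
        cursor = 0
        for delta in deltas:
            skip = int(delta)
            cursor += skip
            if cursor >= len(occurrences):
                raise TagError(
                    f"read {read.name}: MM names base {base!r} beyond its "
                    f"{len(occurrences)} occurrences"
                )
            likelihood = None
            if ml is not None:
                if ml_index >= len(ml):
                    raise TagError(f"read {read.name}: ML shorter than MM calls")
                likelihood = (ml[ml_index] + 0.5) / 256.0
                ml_index += 1
            calls.append(ModificationCall(
                readPos=occurrences[cursor],
                canonicalBase=base,
                modCode=code,
                likelihood=likelihood,
                mode=mode,
            ))
            cursor += 1
    return calls


def encode_modifications(
    read: AlignedRead, calls: Sequence[ModificationCall]
) -> tuple[str, Optional[list[int]]]:
    """Inverse of :func:`decode_modifications`: rebuild MM (and ML) strings."""
    groups: dict[tuple[str, str, str], list[ModificationCall]] = {}
    order: list[tuple[str, str, str]] = []
    for call in calls:
        key = (call.canonicalBase, call.modCode, call.mode)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(call)
    mm_parts = []
    ml_values: list[int] = []
    any_ml = any(c.likelihood is not None for c in calls)
    for key in order:
        base, code, mode = key
        occurrences = _occurrence_positions(read, base)
        rank = {pos: i for i, pos in enumerate(occurrences)}
        ranks = sorted(rank[c.readPos] for c in groups[key])
        deltas = []
        prev = -1
        for r in ranks:
            deltas.append(r - prev - 1)
            prev = r
        # per-group calls are emitted in original-read order; ML follows
        by_rank = sorted(groups[key], key=lambda c: rank[c.readPos])
        for c in by_rank:
            if any_ml:
                v = 0 if c.likelihood is None else int(round(c.likelihood * 256 - 0.5))
                ml_values.append(v)
        mm_parts.append(
            f"{base}+{code}{mode}," + ",".join(str(d) for d in deltas) + ";"
        )
    return "".join(mm_parts), (ml_values if any_ml else None)


# ---------------------------------------------------------------------------
# read policies (filter / sort / color)


_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3, "del": 4}


def apply_read_policies(
    reads: Sequence[AlignedRead],
    filterSpec: Optional[dict] = None,
    sortSpec: Optional[dict] = None,
    colorSpec: Optional[dict] = None,
    at: Optional[int] = None,
) -> list[tuple[AlignedRead, str]]:
    """Filter, stably sort, and color-classify reads.

    filterSpec keys: flags_exclude, flags_require, min_mapq, tag=(name, value).
    sortSpec: {"by": "start" | "base" | "tag", "tag": name} ("base" needs ``at``).
    colorSpec: {"by": "strand" | "mapq" | "insert_size" | "tag" | "modification",
    "tag": name, "thresholds": (lo, hi)}.
    """
    kept = list(reads)
    if filterSpec:
        known = {"flags_exclude", "flags_require", "min_mapq", "tag"}
        unknown = set(filterSpec) - known
        if unknown:
            raise PolicyError(f"unknown filter policy key(s): {sorted(unknown)}")
        if "flags_exclude" in filterSpec:
            mask = int(filterSpec["flags_exclude"])
            kept = [r for r in kept if not (r.flags & mask)]
        if "flags_require" in filterSpec:
            mask = int(filterSpec["flags_require"])
            kept = [r for r in kept if (r.flags & mask) == mask]
        if "min_mapq" in filterSpec:
            kept = [r for r in kept if r.mapq >= int(filterSpec["min_mapq"])]
        if "tag" in filterSpec:
            tag, want = filterSpec["tag"]
            kept = [r for r in kept if r.tags.get(tag) == want]

    if sortSpec:
        by = sortSpec.get("by")
        if by == "start":
            kept.sort(key=lambda r: r.start)
        elif by == "base":
            pos = sortSpec.get("at", at)
            if pos is None:
                raise PolicyError("sort by base requires a reference position")

            def base_key(r: AlignedRead) -> int:
                b = base_at(r, pos) if r.seq is not None else None
                return _BASE_ORDER.get(b, 5)  # A,C,G,T,del then ref/other

            kept.sort(key=base_key)
        elif by == "tag":
            tag = sortSpec.get("tag")
            if not tag:
                raise PolicyError("sort by tag requires a tag name")
            kept.sort(key=lambda r: (r.tags.get(tag) is None,
                                     str(r.tags.get(tag))))
        else:
            raise PolicyError(f"unknown sort policy {by!r}")

    def color_of(r: AlignedRead) -> str:
        if not colorSpec:
            return "default"
        by = colorSpec.get("by")
        if by == "strand":
            return "strand_rev" if r.is_reverse else "strand_fwd"
        if by == "mapq":
            if r.mapq >= 60:
                return "mapq_high"
            if r.mapq >= 30:
                return "mapq_mid"
            if r.mapq > 0:
                return "mapq_low"
            return "mapq_zero"
        if by == "insert_size":
            lo, hi = colorSpec.get("thresholds", (0, 0))
            if r.mate is None:
                return "insert_unpaired"
            size = abs(r.mate[1] - r.start)
            if size < lo:
                return "insert_short"
            if size > hi:
                return "insert_long"
            return "insert_normal"
        if by == "tag":
            tag = colorSpec.get("tag")
            if not tag:
                raise PolicyError("color by tag requires a tag name")
            return f"tag_{tag}_{r.tags.get(tag)}"
        if by == "modification":
            has = ("MM" in r.tags or "Mm" in r.tags) and r.seq is not None
            return "mod_present" if has else "mod_absent"
        raise PolicyError(f"unknown color policy {by!r}")

    return [(r, color_of(r)) for r in kept]


def insert_size_thresholds(reads: Sequence[AlignedRead], n_sd: float = 3.0
                           ) -> tuple[float, float]:
    """Default insert-size color bands: median +/- n_sd robust SDs."""
    sizes = np.array([abs(r.mate[1] - r.start) for r in reads if r.mate],
                     dtype=float)
    if sizes.size == 0:
        return (0.0, 0.0)
    med = float(np.median(sizes))
    sd = float(1.4826 * np.median(np.abs(sizes - med))) or float(sizes.std()) or 1.0
    return (med - n_sd * sd, med + n_sd * sd)
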