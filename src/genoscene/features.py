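"""Readers normalizing annotation and signal formats into unified records.

GFF3/GTF/BED rows become nested :class:`Feature` trees, VCF records become
:class:`VariantFeature` (all samples and genotypes retained, symbolic and
breakend ALTs preserved verbatim), BigWig intervals become binned
:class:`QuantSignal`.  Sequence-derived tracks (GC content windows and
three-frame translation) live here too because they are inputs to the same
track renderers.

All coordinates are converted to 0-based half-open on read; VCF I/O goes
through pysam which handles plain and bgzip/tabix files alike.
"""

from __future__ import annotations

import gzip
import logging
import math
import os
import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FormatError, RegionError
from .genome import Region

log = logging.getLogger("genoscene.features")


@dataclass
class Feature:
    uniqueId: str
    refName: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.'
    type: str = "feature"
    name: Optional[str] = None
    attributes: dict[str, list[str]] = field(default_factory=dict)
    subfeatures: list["Feature"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature {self.uniqueId}: start {self.start} > end {self.end}"
            )

    def walk(self):
        yield self
        for sub in self.subfeatures:
            yield from sub.walk()


@dataclass
class VariantFeature:
    uniqueId: str
    refName: str
    start: int  # 0-based
    end: int
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float] = None
    filter: str = "."
    info: dict = field(default_factory=dict)
    samples: tuple[str, ...] = ()
    genotypes: tuple[dict, ...] = ()  # per-sample FORMAT key -> value
    name: Optional[str] = None
    type: str = "variant"

    @property
    def pos(self) -> int:
        """1-based position as printed in the VCF."""
        return self.start + 1


@dataclass
class QuantSignal:
    region: Region
    binSizeBp: int
    values: list  # one float or None per bin

    def __post_init__(self) -> None:
        expected = n_bins(self.region.length, self.binSizeBp)
        if len(self.values) != expected:
            raise FormatError(
                f"QuantSignal expects {expected} bins, got {len(self.values)}"
            )


def n_bins(length_bp: int, bin_size_bp: int) -> int:
    if bin_size_bp < 1:
        raise FormatError("binSizeBp must be >= 1")
    return math.ceil(length_bp / bin_size_bp)


# ---------------------------------------------------------------------------
# annotation formats


def _open_text(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _overlaps(f: Feature, region: Region) -> bool:
    return f.refName == region.refName and f.start < region.end and f.end > region.start


def read_features(
    path: str,
    format: Optional[str] = None,
    region: Optional[Region] = None,
) -> list[Feature]:
    """Read GFF3/GTF/BED into nested features overlapping ``region``.

    Format is inferred from the file name when not given.  For
    bgzip-compressed, tabix-indexed files with a region, only the indexed
    slice is scanned; parent/child assembly then happens on that slice.
    """
    fmt = format or _infer_format(path)
    lines = _feature_lines(path, region)
    if fmt == "gff3":
        feats = _assemble_gff3(lines)
    elif fmt == "gtf":
        feats = _assemble_gtf(lines)
    elif fmt == "bed":
        feats = _parse_bed(lines)
    else:
        raise FormatError(f"unknown feature format {fmt!r}")
    if region is not None:
        feats = [f for f in feats if _overlaps(f, region)]
    return feats


def _infer_format(path: str) -> str:
    base = path[:-3] if path.endswith(".gz") else path
    ext = os.path.splitext(base)[1].lower().lstrip(".")
    if ext in ("gff", "gff3"):
        return "gff3"
    if ext == "gtf":
        return "gtf"
    if ext == "bed":
        return "bed"
    raise FormatError(f"cannot infer feature format from {path!r}")


def _feature_lines(path: str, region: Optional[Region]) -> list[tuple[int, str]]:
    """Numbered data lines, via tabix when possible."""
    if region is not None and path.endswith(".gz"):
        for idx_ext in (".tbi", ".csi"):
            if os.path.exists(path + idx_ext):
                import pysam

                with pysam.TabixFile(path) as tbx:
                    if region.refName not in tbx.contigs:
                        return []
                    return [
                        (0, line)
                        for line in tbx.fetch(region.refName, region.start, region.end)
                    ]
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line))
    return out


def _split9(lineno: int, line: str) -> list[str]:
    cols = line.split("\t")
    if len(cols) != 9:
        raise FormatError(f"line {lineno}: expected 9 tab-separated columns")
    return cols


def _gff3_attributes(text: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key] = [urllib.parse.unquote(v) for v in value.split(",")]
    return attrs


def _assemble_gff3(lines: Iterable[tuple[int, str]]) -> list[Feature]:
    rows = []
    by_id: dict[str, Feature] = {}
    for lineno, line in lines:
        cols = _split9(lineno, line)
        try:
            start, end = int(cols[3]) - 1, int(cols[4])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad coordinates") from exc
        attrs = _gff3_attributes(cols[8])
        fid = attrs.get("ID", [None])[0]
        feat = Feature(
            uniqueId=fid or f"{cols[0]}:{start}-{end}:{lineno}",
            refName=cols[0],
            start=start,
            end=end,
            strand=cols[6] if cols[6] in "+-" else ".",
            type=cols[2],
            name=attrs.get("Name", [None])[0],
            attributes=attrs,
        )
        rows.append((feat, attrs.get("Parent", [])))
        if fid is not None:
            by_id[fid] = feat
    top: list[Feature] = []
    for feat, parents in rows:
        if not parents:
            top.append(feat)
            continue
        if len(parents) > 1:
            log.info("feature %s has %d parents; duplicated under each",
                     feat.uniqueId, len(parents))
        placed = False
        for pid in parents:
            parent = by_id.get(pid)
            if parent is None:
                continue
            if not (parent.start <= feat.start and feat.end <= parent.end):
                log.warning("feature %s extends outside parent %s",
                            feat.uniqueId, pid)
            parent.subfeatures.append(feat)
            placed = True
        if not placed:
            log.warning("feature %s references missing Parent(s) %s",
                        feat.uniqueId, parents)
            top.append(feat)
    return top


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _assemble_gtf(lines: Iterable[tuple[int, str]]) -> list[Feature]:
    """gene -> transcript -> exon/CDS assembly from gene_id/transcript_id."""
    genes: dict[str, Feature] = {}
    transcripts: dict[str, Feature] = {}
    order: list[str] = []
    for lineno, line in lines:
        cols = _split9(lineno, line)
        ftype = cols[2]
        if ftype not in ("gene", "transcript", "exon", "CDS"):
            continue
        attrs = {k: [v] for k, v in _GTF_ATTR.findall(cols[8])}
        gid = attrs.get("gene_id", [None])[0]
        tid = attrs.get("transcript_id", [None])[0]
        if gid is None:
            raise FormatError(f"line {lineno}: GTF record without gene_id")
        start, end = int(cols[3]) - 1, int(cols[4])
        strand = cols[6] if cols[6] in "+-" else "."
        if gid not in genes:
            genes[gid] = Feature(gid, cols[0], start, end, strand, "gene",
                                 attrs.get("gene_name", [gid])[0], attrs)
            order.append(gid)
        gene = genes[gid]
        gene.start, gene.end = min(gene.start, start), max(gene.end, end)
        if ftype == "gene":
            gene.attributes = attrs
            continue
        if tid is None:
            raise FormatError(f"line {lineno}: GTF {ftype} without transcript_id")
        if tid not in transcripts:
            transcripts[tid] = Feature(tid, cols[0], start, end, strand,
                                       "transcript", tid, attrs)
            gene.subfeatures.append(transcripts[tid])
        tx = transcripts[tid]
        tx.start, tx.end = min(tx.start, start), max(tx.end, end)
        if ftype in ("exon", "CDS"):
            tx.subfeatures.append(
                Feature(f"{tid}:{ftype}:{start}", cols[0], start, end,
                        strand, ftype, None, attrs)
            )
    for gid in order:
        gene = genes[gid]
        for tx in gene.subfeatures:
            tx.subfeatures.sort(key=lambda f: (f.start, f.end))
    return [genes[g] for g in order]


def _parse_bed(lines: Iterable[tuple[int, str]]) -> list[Feature]:
    feats = []
    for lineno, line in lines:
        if line.startswith(("track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(f"line {lineno}: BED needs >= 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad BED coordinates") from exc
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
        feat = Feature(
            uniqueId=name or f"{cols[0]}:{start}-{end}:{lineno}",
            refName=cols[0], start=start, end=end, strand=strand,
            type="region", name=name,
        )
        if len(cols) > 4 and cols[4] not in (".", ""):
            feat.attributes["score"] = [cols[4]]
        if len(cols) >= 12:  # BED12 blocks become exon-like children
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            for i, (bs, bl) in enumerate(zip(starts, sizes)):
                feat.subfeatures.append(
                    Feature(f"{feat.uniqueId}:block{i}", cols[0],
                            start + bs, start + bs + bl, strand, "block")
                )
        feats.append(feat)
    return feats


def write_gff3(features: Iterable[Feature], path: str) -> None:
    """Serialize nested features back to GFF3 (round-trips with read_features)."""

    def esc(v: str) -> str:
        return urllib.parse.quote(v, safe=" :^*$@!+?|")

    def emit(fh, feat: Feature, parent: Optional[str]) -> None:
        attrs = dict(feat.attributes)
        attrs["ID"] = [feat.uniqueId]
        if feat.name is not None:
            attrs["Name"] = [feat.name]
        if parent is not None:
            attrs["Parent"] = [parent]
        elif "Parent" in attrs:
            del attrs["Parent"]
        col9 = ";".join(
            f"{k}={','.join(esc(v) for v in vs)}" for k, vs in sorted(attrs.items())
        )
        fh.write("\t".join([
            feat.refName, "genoscene", feat.type, str(feat.start + 1),
            str(feat.end), ".", feat.strand if feat.strand in "+-" else ".",
            ".", col9,
        ]) + "\n")
        for sub in feat.subfeatures:
            emit(fh, sub, feat.uniqueId)

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            emit(fh, feat, None)


# ---------------------------------------------------------------------------
# VCF


def read_variants(path: str, region: Optional[Region] = None) -> list[VariantFeature]:
    """Read VCF 4.x records, keeping every sample's genotypes.

    Symbolic (``<DEL>`` etc.) and breakend ALT strings are preserved verbatim
    for the SV toolkit.  ``end`` honors INFO END for symbolic alleles, else
    ``start + len(ref)``.
    """
    import pysam

    out: list[VariantFeature] = []
    with pysam.VariantFile(path) as vcf:
        sample_names = tuple(vcf.header.samples)
        if region is not None and vcf.index is not None:
            records = vcf.fetch(region.refName, region.start, region.end)
            region_filter = False
        else:
            records = vcf
            region_filter = region is not None
        for rec in records:
            start = rec.start
            end = rec.stop  # pysam applies INFO END / ref-length semantics
            if region_filter and not (
                rec.chrom == region.refName and start < region.end and end > region.start
            ):
                continue
            info = {}
            for key, value in rec.info.items():
                info[key] = list(value) if isinstance(value, tuple) else value
            genotypes = []
            for s in sample_names:
                call = rec.samples[s]
                gmap = {}
                for key, value in call.items():
                    if key == "GT":
                        sep = "|" if call.phased else "/"
                        gmap["GT"] = sep.join(
                            "." if a is None else str(a) for a in value
                        )
                    elif isinstance(value, tuple):
                        gmap[key] = list(value)
                    else:
                        gmap[key] = value
                genotypes.append(gmap)
            out.append(VariantFeature(
                uniqueId=rec.id or f"{rec.chrom}:{rec.pos}:{len(out)}",
                refName=rec.chrom,
                start=start,
                end=end,
                ref=rec.ref or "",
                alts=tuple(rec.alts or ()),
                qual=rec.qual,
                filter=";".join(rec.filter.keys()) or ".",
                info=info,
                samples=sample_names,
                genotypes=tuple(genotypes),
                name=rec.id,
            ))
    return out


# ---------------------------------------------------------------------------
# quantitative signal


def read_quant(path: str, region: Region, binSizeBp: int) -> QuantSignal:
    """Bin a BigWig over ``region``: per-bin mean of covered bases.

    Bases without a value are excluded from the mean; a bin with no covered
    base is reported as None (missing).
    """
    import numpy as np
    import pyBigWig

    bw = pyBigWig.open(path)
    try:
        chroms = bw.chroms()
        if region.refName not in chroms:
            raise RegionError(f"chromosome {region.refName!r} not in BigWig")
        if region.end > chroms[region.refName]:
            raise RegionError(
                f"region end {region.end} beyond chromosome length "
                f"{chroms[region.refName]}"
            )
        vals = np.asarray(bw.values(region.refName, region.start, region.end))
    finally:
        bw.close()
    values = []
    for b in range(n_bins(region.length, binSizeBp)):
        chunk = vals[b * binSizeBp:(b + 1) * binSizeBp]
        covered = chunk[~np.isnan(chunk)]
        values.append(float(covered.mean()) if covered.size else None)
    return QuantSignal(region, binSizeBp, values)


def gc_content(
    sequence: str,
    windowBp: int,
    stepBp: Optional[int] = None,
    region: Optional[Region] = None,
) -> QuantSignal:
    """GC fraction per window; N (and other non-ACGT) excluded from the denominator."""
    if windowBp < 1:
        raise FormatError("windowBp must be >= 1")
    step = stepBp or windowBp
    seq = sequence.upper()
    values = []
    for start in range(0, len(seq), step):
        window = seq[start:start + windowBp]
        gc = sum(1 for b in window if b in "GC")
        denom = sum(1 for b in window if b in "ACGT")
        values.append(gc / denom if denom else None)
    reg = region or Region("seq", 0, len(seq))
    return QuantSignal(reg, step, values)


def three_frame_translation(sequence: str) -> tuple[str, str, str]:
    """Peptides for reading frames 0, 1, 2 of the given strand.

    Standard genetic code; IUPAC ambiguity codes that do not resolve to one
    amino acid become X; the trailing partial codon is dropped.
    """
    from Bio.Seq import Seq

    frames = []
    for offset in range(3):
        sub = sequence[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        frames.append(str(Seq(sub).translate()) if sub else "")
    return tuple(frames)
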