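"""Assemblies, regions, and the discontiguous-view coordinate transform.

An :class:`Assembly` names an ordered set of reference sequences, an alias
map (so ``1`` and ``chr1`` can be treated identically when an alias file says
so), and optional cytobands for ideogram rendering.  A
:class:`DisplayedRegions` is an ordered, possibly discontiguous stack of
regions — the coordinate backbone every linear renderer shares.  All
internal coordinates are 0-based half-open; 1-based conventions appear only
at locstring and VCF boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .errors import RegionError, UnknownNameError

log = logging.getLogger("genoscene.genome")

#: sentinel returned by px_to_bp for offsets inside inter-region padding
GAP = "__inter_region_gap__"


@dataclass(frozen=True)
class Cytoband:
    refName: str
    start: int
    end: int
    name: str
    stain: str  # gieStain class, e.g. gneg / gpos50 / acen


@dataclass(frozen=True)
class Region:
    """Half-open interval on a canonical reference sequence.

    ``reversed`` flips the drawing direction, not the coordinates: start/end
    stay on the forward strand.
    """

    refName: str
    start: int
    end: int
    reversed: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise RegionError(
                f"invalid region {self.refName}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, refName: str, coord: int) -> bool:
        return refName == self.refName and self.start <= coord < self.end

    def overlaps(self, refName: str, start: int, end: int) -> bool:
        return refName == self.refName and start < self.end and end > self.start


class Assembly:
    """Named collection of reference sequences with aliases and cytobands."""

    def __init__(
        self,
        name: str,
        sequences: Sequence[tuple[str, int]],
        aliases: Optional[dict[str, str]] = None,
        cytobands: Optional[Iterable[Cytoband]] = None,
    ) -> None:
        self.name = name
        self.sequences: list[tuple[str, int]] = list(sequences)
        self._lengths = dict(self.sequences)
        if len(self._lengths) != len(self.sequences):
            raise RegionError(f"assembly {name!r}: duplicate canonical refNames")
        self.aliases: dict[str, str] = dict(aliases or {})
        for alias, canonical in self.aliases.items():
            if canonical not in self._lengths:
                raise UnknownNameError(
                    f"alias {alias!r} maps to unknown sequence {canonical!r}"
                )
            if alias in self._lengths and alias != canonical:
                raise RegionError(
                    f"alias {alias!r} collides with a different canonical name"
                )
        self.cytobands: list[Cytoband] = list(cytobands or [])
        for band in self.cytobands:
            length = self._lengths.get(band.refName)
            if length is None or not (0 <= band.start <= band.end <= length):
                raise RegionError(
                    f"cytoband {band.name!r} outside {band.refName!r} bounds"
                )

    # -- name handling -----------------------------------------------------

    def canonical(self, name: str) -> str:
        """Resolve ``name`` (canonical or alias; case-sensitive) to canonical."""
        if name in self._lengths:
            return name
        if name in self.aliases:
            return self.aliases[name]
        raise UnknownNameError(
            f"unknown sequence name {name!r} in assembly {self.name!r}"
        )

    def seq_length(self, name: str) -> int:
        return self._lengths[self.canonical(name)]

    def whole_region(self, name: str) -> Region:
        canonical = self.canonical(name)
        return Region(canonical, 0, self._lengths[canonical])

    def bands_for(self, refName: str) -> list[Cytoband]:
        canonical = self.canonical(refName)
        return [b for b in self.cytobands if b.refName == canonical]

    # -- loading -----------------------------------------------------------

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str,
        name: Optional[str] = None,
        aliases_path: Optional[str] = None,
        cytoband_path: Optional[str] = None,
    ) -> "Assembly":
        """Build an assembly from FASTA (+.fai, created on demand).

        The alias file has one line per sequence: canonical name, then
        tab-separated aliases.  The cytoband file uses UCSC cytoBand.txt
        columns (chrom, start, end, name, gieStain).
        """
        import pysam

        with pysam.FastaFile(fasta_path) as fa:
            sequences = list(zip(fa.references, fa.lengths))
        aliases: dict[str, str] = {}
        if aliases_path:
            with open(aliases_path) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if not parts or not parts[0]:
                        continue
                    canonical = parts[0]
                    for alias in parts[1:]:
                        if alias:
                            aliases[alias] = canonical
        cytobands: list[Cytoband] = []
        if cytoband_path:
            with open(cytoband_path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    chrom, start, end, band, stain = line.rstrip("\n").split("\t")[:5]
                    cytobands.append(Cytoband(chrom, int(start), int(end), band, stain))
        return cls(name or fasta_path, sequences, aliases, cytobands)


def canonical_refname(name: str, assembly: Assembly) -> str:
    """Functional alias for :meth:`Assembly.canonical`."""
    return assembly.canonical(name)


class DisplayedRegions:
    """Ordered stack of regions forming one horizontal coordinate system.

    Region order is significant and duplicate refNames are permitted (e.g.
    chr3 and chr4 side by side, or the same window shown twice).  Boundaries
    between consecutive regions are separated by ``interRegionPadding``
    pixels.
    """

    def __init__(
        self,
        regions: Sequence[Region],
        interRegionPadding: float = 2.0,
        assembly: Optional[Assembly] = None,
    ) -> None:
        self.regions: list[Region] = list(regions)
        self.interRegionPadding = float(interRegionPadding)
        if assembly is not None:
            self.validate(assembly)
        seen: set[tuple[str, int, int]] = set()
        for r in self.regions:
            key = (r.refName, r.start, r.end)
            if key in seen:
                log.info("region %s:%d-%d displayed more than once", *key)
            seen.add(key)

    def validate(self, assembly: Assembly) -> None:
        for r in self.regions:
            length = assembly.seq_length(r.refName)
            if r.end > length:
                raise RegionError(
                    f"region {r.refName}:{r.start}-{r.end} exceeds length {length}"
                )

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)

    def width_px(self, bpPerPx: float) -> float:
        pad = self.interRegionPadding * max(0, len(self.regions) - 1)
        return self.total_bp() / bpPerPx + pad

    def bp_per_px_for_width(self, widthPx: float) -> float:
        pad = self.interRegionPadding * max(0, len(self.regions) - 1)
        usable = widthPx - pad
        total = self.total_bp()
        if usable <= 0 or total == 0:
            raise RegionError("view too narrow for the displayed regions")
        return total / usable

    # -- the transform -----------------------------------------------------

    def bp_to_px(
        self, refName: str, coord: int, bpPerPx: float
    ) -> Optional[float]:
        """Horizontal pixel offset of a base, or None if not displayed.

        The offset points at the left edge of the base's pixel span (for a
        reversed region, at the edge nearer the view's left, i.e. the base's
        mirrored position).  The first region containing the coordinate wins
        when duplicates overlap.
        """
        if bpPerPx <= 0:
            raise RegionError("bpPerPx must be positive")
        base_px = 0.0
        for i, r in enumerate(self.regions):
            if i > 0:
                base_px += self.interRegionPadding
            if r.contains(refName, coord):
                within = (r.end - 1 - coord) if r.reversed else (coord - r.start)
                return base_px + within / bpPerPx
            base_px += r.length / bpPerPx
        return None

    def bp_to_px_edge(
        self, refName: str, coord: float, bpPerPx: float
    ) -> Optional[float]:
        """Continuous variant of bp_to_px that also accepts coord == region.end,
        mapping it to the region's right edge (left edge when reversed).
        Used by renderers to place span edges; bp_to_px remains the base-level
        transform."""
        if bpPerPx <= 0:
            raise RegionError("bpPerPx must be positive")
        base_px = 0.0
        for i, r in enumerate(self.regions):
            if i > 0:
                base_px += self.interRegionPadding
            if r.refName == refName and r.start <= coord <= r.end:
                within = (r.end - coord) if r.reversed else (coord - r.start)
                return base_px + within / bpPerPx
            base_px += r.length / bpPerPx
        return None

    def px_to_bp(
        self, offsetPx: float, bpPerPx: float
    ) -> Union[tuple[str, int], str]:
        """Inverse of bp_to_px on region interiors.

        Returns ``(refName, coord)`` or the :data:`GAP` marker when the
        offset falls inside inter-region padding.  Raises for offsets
        outside the view.
        """
        if bpPerPx <= 0:
            raise RegionError("bpPerPx must be positive")
        if offsetPx < 0 or offsetPx > self.width_px(bpPerPx) + 1e-9:
            raise RegionError(f"pixel offset {offsetPx} outside the view")
        base_px = 0.0
        for i, r in enumerate(self.regions):
            region_px = r.length / bpPerPx
            is_last = i == len(self.regions) - 1
            inside = offsetPx < base_px + region_px - 1e-9 or (
                is_last and offsetPx <= base_px + region_px + 1e-9
            )
            if r.length > 0 and inside:
                within = int(math.floor((offsetPx - base_px) * bpPerPx + 1e-6))
                within = min(max(within, 0), r.length - 1)
                coord = (r.end - 1 - within) if r.reversed else (r.start + within)
                return (r.refName, coord)
            base_px += region_px
            if i < len(self.regions) - 1:
                if offsetPx < base_px + self.interRegionPadding - 1e-9:
                    return GAP
                base_px += self.interRegionPadding
        return GAP


def total_bp(displayed: DisplayedRegions) -> int:
    """Sum of region lengths across the stack."""
    return displayed.total_bp()


def bp_to_px(
    refName: str, coord: int, displayed: DisplayedRegions, bpPerPx: float
) -> Optional[float]:
    return displayed.bp_to_px(refName, coord, bpPerPx)


def px_to_bp(
    offsetPx: float, displayed: DisplayedRegions, bpPerPx: float
) -> Union[tuple[str, int], str]:
    return displayed.px_to_bp(offsetPx, bpPerPx)
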