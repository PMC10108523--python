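"""Deterministic SVG scene construction for every view type.

This is the only module that knows about pixels.  A :class:`SvgScene` is an
ordered list of per-track/per-layer groups of primitive shapes; serializing
the same scene twice is byte-identical (attributes are emitted in sorted
order, floats with a fixed format, ids assigned sequentially — no timestamps,
no unordered traversal).

Views: linear genome, circular (Circos-style chords), dotplot, stacked
linear synteny, breakpoint split, and chromosome ideograms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import RenderError
from .genome import Assembly, DisplayedRegions, Region
from .sv import LEFT_OF_POS, Connector, SVEvent
from .synteny import SyntenyBlock, dotplot_path

log = logging.getLogger("genoscene.svg")

# default palette; Fig-style conventions: black connectors, green variant
# lines, blue soft clips, purple insertions
PALETTE = {
    "feature": "#1f77b4",
    "quant": "#808080",
    "read": "#b0b0b0",
    "read_rev": "#9999cc",
    "softclip": "#0000ff",
    "insertion": "#800080",
    "variant": "#cc4444",
    "connector": "#000000",
    "variant_line": "#00aa00",
    "chord": "#333333",
    "synteny": "#888888cc",
}

ROW_HEIGHT_PX = 8
ROW_PADDING_PX = 1


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if not math.isfinite(value):
            raise RenderError(f"non-finite coordinate {value!r}")
        text = f"{value:.3f}".rstrip("0").rstrip(".")
        return "0" if text in ("-0", "") else text
    return str(value)


_ESCAPES = {"&": "&amp;", "<": "&lt;", ">": "&gt;", '"': "&quot;"}


def _esc(text: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in str(text))


class SvgScene:
    """Ordered, deterministic vector scene with per-track groups."""

    def __init__(self, widthPx: float, heightPx: float) -> None:
        if widthPx <= 0 or heightPx <= 0:
            raise RenderError("scene must have positive width and height")
        self.widthPx = widthPx
        self.heightPx = heightPx
        self._groups: list[tuple[str, list[dict]]] = []
        self._group_index: dict[str, list[dict]] = {}
        self._ids: set[str] = set()
        self._counter = 0

    def group(self, gid: str) -> list[dict]:
        if gid not in self._group_index:
            bucket: list[dict] = []
            self._groups.append((gid, bucket))
            self._group_index[gid] = bucket
        return self._group_index[gid]

    def add(self, gid: str, tag: str, attrs: Optional[dict] = None,
            elem_id: Optional[str] = None, text: Optional[str] = None) -> str:
        attrs = dict(attrs or {})
        if elem_id is None:
            self._counter += 1
            elem_id = f"{gid}-{self._counter}"
        if elem_id in self._ids:
            raise RenderError(f"duplicate element id {elem_id!r}")
        self._ids.add(elem_id)
        for key, value in attrs.items():
            if isinstance(value, float) and not math.isfinite(value):
                raise RenderError(f"non-finite attribute {key}={value}")
        self.group(gid).append(
            {"tag": tag, "attrs": attrs, "id": elem_id, "text": text}
        )
        return elem_id

    def elements(self, gid: Optional[str] = None,
                 cls: Optional[str] = None) -> list[dict]:
        out = []
        for name, bucket in self._groups:
            if gid is not None and name != gid:
                continue
            for el in bucket:
                if cls is not None:
                    classes = str(el["attrs"].get("class", "")).split()
                    if cls not in classes:
                        continue
                out.append(el)
        return out

    def to_svg(self) -> str:
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(self.widthPx)}" height="{_fmt(self.heightPx)}" '
            f'viewBox="0 0 {_fmt(self.widthPx)} {_fmt(self.heightPx)}">',
        ]
        for gid, bucket in self._groups:
            lines.append(f'  <g id="{_esc(gid)}">')
            for el in bucket:
                attrs = dict(el["attrs"])
                attrs["id"] = el["id"]
                rendered = " ".join(
                    f'{k}="{_esc(_fmt(v))}"' for k, v in sorted(attrs.items())
                )
                if el["text"] is None:
                    lines.append(f'    <{el["tag"]} {rendered}/>')
                else:
                    lines.append(
                        f'    <{el["tag"]} {rendered}>{_esc(el["text"])}</{el["tag"]}>'
                    )
            lines.append("  </g>")
        lines.append("</svg>")
        return "\n".join(lines) + "\n"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_svg())


# ---------------------------------------------------------------------------
# linear view


def tick_spacing_bp(viewWidthBp: int) -> int:
    """Major ticks at the largest power of ten <= viewWidthBp / 5."""
    if viewWidthBp < 5:
        return 1
    return 10 ** int(math.floor(math.log10(viewWidthBp / 5)))


def format_bp(coord: int) -> str:
    """1-based label with thin-space thousands grouping."""
    return f"{coord:,}".replace(",", " ")


def _draw_ruler(scene: SvgScene, gid: str, displayed: DisplayedRegions,
                bpPerPx: float, y0: float) -> float:
    spacing = tick_spacing_bp(displayed.total_bp() or 1)
    for region in displayed:
        first = ((region.start + spacing - 1) // spacing) * spacing
        for coord in range(first, region.end, spacing):
            x = displayed.bp_to_px(region.refName, coord, bpPerPx)
            if x is None:
                continue
            scene.add(gid, "line", {
                "class": "tick", "x1": x, "x2": x,
                "y1": y0 + 12, "y2": y0 + 18, "stroke": "#333333",
            })
            scene.add(gid, "text", {
                "class": "tick-label", "x": x, "y": y0 + 10,
                "font-size": 8, "text-anchor": "middle",
            }, text=format_bp(coord + 1))
        # region name label at the left edge of the region
        x_left = displayed.bp_to_px_edge(region.refName, region.start, bpPerPx)
        if region.reversed:
            x_left = displayed.bp_to_px_edge(region.refName, region.end, bpPerPx)
        scene.add(gid, "text", {
            "class": "region-label", "x": x_left + 1, "y": y0 + 18,
            "font-size": 7, "text-anchor": "start", "fill": "#666666",
        }, text=region.refName + (" (rev)" if region.reversed else ""))
    return y0 + 20


def _draw_separators(scene: SvgScene, gid: str, displayed: DisplayedRegions,
                     bpPerPx: float, height: float) -> None:
    base = 0.0
    for i, region in enumerate(displayed):
        if i > 0:
            x = base + displayed.interRegionPadding / 2.0
            scene.add(gid, "line", {
                "class": "separator", "x1": x, "x2": x, "y1": 0, "y2": height,
                "stroke": "#cccccc",
            })
            base += displayed.interRegionPadding
        base += region.length / bpPerPx


def _span_px(displayed: DisplayedRegions, refName: str, start: int, end: int,
             bpPerPx: float) -> list[tuple[float, float]]:
    """Pixel (x, width) spans of a feature interval, one per overlapped region."""
    spans = []
    for region in displayed:
        if not region.overlaps(refName, start, end):
            continue
        lo, hi = max(start, region.start), min(end, region.end)
        x1 = displayed.bp_to_px_edge(refName, lo, bpPerPx)
        x2 = displayed.bp_to_px_edge(refName, hi, bpPerPx)
        if x1 is None or x2 is None:
            continue
        spans.append((min(x1, x2), abs(x2 - x1)))
    return spans


def _draw_track(scene: SvgScene, displayed: DisplayedRegions, bpPerPx: float,
                track: dict, y0: float) -> float:
    """Draw one prepared track; returns the y after the track."""
    from . import alignments as aln

    gid = f"track-{track['trackId']}"
    ttype = track["type"]
    data = track.get("data")
    opts = track.get("options", {})

    if ttype == "feature":
        layout = {}
        intervals = sorted(
            ((f.uniqueId, f.start, f.end) for f in data),
            key=lambda t: (t[1], -(t[2] - t[1]), t[0]),
        )
        layout = aln.assign_rows(intervals, paddingBp=0).rowOf
        rows = 0
        for feat in data:
            row = layout[feat.uniqueId]
            rows = max(rows, row + 1)
            y = y0 + row * (ROW_HEIGHT_PX + ROW_PADDING_PX)
            for x, w in _span_px(displayed, feat.refName, feat.start, feat.end,
                                 bpPerPx):
                scene.add(gid, "rect", {
                    "class": "feature", "x": x, "y": y,
                    "width": max(w, 0.5), "height": ROW_HEIGHT_PX,
                    "fill": PALETTE["feature"],
                }, elem_id=f"{gid}-f-{feat.uniqueId}-{_fmt(x)}")
                if feat.strand in "+-":
                    tip = x + w if feat.strand == "+" else x
                    back = tip - 3 if feat.strand == "+" else tip + 3
                    scene.add(gid, "path", {
                        "class": "feature-arrow",
                        "d": f"M {_fmt(back)} {_fmt(y)} L {_fmt(tip)} "
                             f"{_fmt(y + ROW_HEIGHT_PX / 2)} L {_fmt(back)} "
                             f"{_fmt(y + ROW_HEIGHT_PX)}",
                        "fill": "none", "stroke": PALETTE["feature"],
                    })
        return y0 + max(rows, 1) * (ROW_HEIGHT_PX + ROW_PADDING_PX) + 4

    if ttype == "quantitative":
        height = opts.get("height", 40)
        signals = data if isinstance(data, (list, tuple)) else [data]
        present = [v for s in signals for v in s.values if v is not None]
        vmax = (max(present) if present else 1.0) or 1.0
        for signal in signals:
            for i, value in enumerate(signal.values):
                if value is None:
                    continue
                s = signal.region.start + i * signal.binSizeBp
                e = min(s + signal.binSizeBp, signal.region.end)
                for x, w in _span_px(displayed, signal.region.refName, s, e,
                                     bpPerPx):
                    h = height * value / vmax
                    scene.add(gid, "rect", {
                        "class": "quant-bar", "x": x, "y": y0 + height - h,
                        "width": max(w, 0.5), "height": h,
                        "fill": PALETTE["quant"],
                    })
        return y0 + height + 4

    if ttype == "alignments":
        reads = data
        if track.get("filter") or track.get("sort") or track.get("color"):
            colored = aln.apply_read_policies(
                reads, track.get("filter"), track.get("sort"),
                track.get("color"), at=track.get("at"))
        else:
            colored = [(r, "default") for r in reads]
        reads = [r for r, _ in colored]
        color_of = {r.uniqueId: c for r, c in colored}
        layout = aln.layout_reads(reads, paddingBp=opts.get("paddingBp", 2))
        min_ins = opts.get("min_insertion", 1)
        for read in reads:
            row = layout.rowOf[read.uniqueId]
            y = y0 + row * (ROW_HEIGHT_PX + ROW_PADDING_PX)
            for x, w in _span_px(displayed, read.refName, read.start,
                                 read.ref_end, bpPerPx):
                cls = color_of[read.uniqueId]
                fill = PALETTE["read_rev"] if read.is_reverse else PALETTE["read"]
                scene.add(gid, "rect", {
                    "class": f"read {cls}", "x": x, "y": y,
                    "width": max(w, 0.5), "height": ROW_HEIGHT_PX, "fill": fill,
                })
            for pos, length, side in aln.find_softclip_markers(read):
                x = displayed.bp_to_px_edge(read.refName, pos, bpPerPx)
                if x is None:
                    continue
                scene.add(gid, "rect", {
                    "class": f"softclip softclip-{side}",
                    "x": x - 1, "y": y, "width": 2, "height": ROW_HEIGHT_PX,
                    "fill": PALETTE["softclip"],
                })
            for pos, length in aln.find_insertions(read, min_ins):
                x = displayed.bp_to_px_edge(read.refName, pos, bpPerPx)
                if x is None:
                    continue
                scene.add(gid, "rect", {
                    "class": "insertion", "x": x - 1, "y": y,
                    "width": 2, "height": ROW_HEIGHT_PX,
                    "fill": PALETTE["insertion"],
                })
        return y0 + max(layout.rowCount, 1) * (ROW_HEIGHT_PX + ROW_PADDING_PX) + 4

    if ttype == "variant":
        for v in data:
            for x, w in _span_px(displayed, v.refName, v.start, max(v.end, v.start + 1),
                                 bpPerPx):
                scene.add(gid, "rect", {
                    "class": "variant", "x": x, "y": y0,
                    "width": max(w, 1.0), "height": ROW_HEIGHT_PX,
                    "fill": PALETTE["variant"],
                })
        return y0 + ROW_HEIGHT_PX + 4

    if ttype == "reference":
        sequences = data or {}
        base_colors = {"A": "#00bb00", "C": "#0000bb", "G": "#bb7700",
                       "T": "#bb0000"}
        if bpPerPx <= 1.0:
            for region in displayed:
                seq = sequences.get(region.refName, "")
                for coord in range(region.start, min(region.end, len(seq))):
                    base = seq[coord].upper()
                    x = displayed.bp_to_px(region.refName, coord, bpPerPx)
                    scene.add(gid, "rect", {
                        "class": f"base base-{base}", "x": x, "y": y0,
                        "width": 1.0 / bpPerPx, "height": ROW_HEIGHT_PX,
                        "fill": base_colors.get(base, "#999999"),
                    })
        else:
            scene.add(gid, "rect", {
                "class": "sequence-overview", "x": 0, "y": y0,
                "width": displayed.width_px(bpPerPx), "height": ROW_HEIGHT_PX,
                "fill": "#dddddd",
            })
        return y0 + ROW_HEIGHT_PX + 4

    raise RenderError(f"unknown track type {ttype!r}")


def render_linear(
    displayed: DisplayedRegions,
    tracks: Sequence[dict] = (),
    widthPx: float = 800.0,
    bpPerPx: Optional[float] = None,
    heightPx: Optional[float] = None,
) -> SvgScene:
    """Linear genome view: ruler, region separators, then one group per track.

    ``tracks`` entries are prepared dicts: ``{"trackId", "type", "data",
    "options": {...}}`` with data already fetched and normalized.
    """
    if widthPx <= 0:
        raise RenderError("zero-width view")
    if displayed.total_bp() == 0:
        raise RenderError("displayed regions are empty")
    if bpPerPx is None:
        bpPerPx = displayed.bp_per_px_for_width(widthPx)
    else:
        widthPx = displayed.width_px(bpPerPx)
    # first pass to measure height
    probe = SvgScene(widthPx, 10_000)
    y = _draw_ruler(probe, "ruler", displayed, bpPerPx, 0.0)
    for track in tracks:
        y = _draw_track(probe, displayed, bpPerPx, track, y)
    total_height = heightPx or (y + 4)
    scene = SvgScene(widthPx, total_height)
    y = _draw_ruler(scene, "ruler", displayed, bpPerPx, 0.0)
    for track in tracks:
        y = _draw_track(scene, displayed, bpPerPx, track, y)
    _draw_separators(scene, "separators", displayed, bpPerPx, total_height)
    return scene


# ---------------------------------------------------------------------------
# circular view


@dataclass
class CircleLayout:
    """Angular layout of regions around a circle.

    Angles are radians measured clockwise from ``rotationOffset`` (SVG y
    grows downward, so the standard (cos, sin) parametrization traces
    clockwise on screen).  Sum of spans is 2*pi - n*gapAngle.
    """

    entries: list[tuple[Region, float, float]]
    radiusPx: float
    gapAngle: float

    def bp_to_angle(self, refName: str, coord: float) -> Optional[float]:
        for region, a0, a1 in self.entries:
            if region.refName == refName and region.start <= coord <= region.end:
                if region.length == 0:
                    return a0
                frac = (coord - region.start) / region.length
                return a0 + frac * (a1 - a0)
        return None


def layout_circle(
    regions: Sequence[Region],
    gapAngle: float = 0.0,
    rotationOffset: float = 0.0,
    radiusPx: float = 200.0,
) -> CircleLayout:
    """Assign each region an angular span proportional to its length."""
    total = sum(r.length for r in regions)
    if total <= 0:
        raise RenderError("layout_circle needs positive total length")
    n = len(regions)
    available = 2 * math.pi - n * gapAngle
    if available <= 0:
        raise RenderError("gapAngle leaves no room for regions")
    entries = []
    angle = rotationOffset
    for region in regions:
        span = available * region.length / total
        entries.append((region, angle, angle + span))
        angle += span + gapAngle
    return CircleLayout(entries=entries, radiusPx=radiusPx, gapAngle=gapAngle)


def render_circular(
    layout: CircleLayout,
    events: Sequence[SVEvent] = (),
    marginPx: float = 30.0,
    chord_pull: float = 0.2,
) -> SvgScene:
    """Circos-style view: one arc per region, one chord per two-ended event.

    Chord endpoints lie exactly on the layout radius; the quadratic control
    point is the endpoint midpoint pulled toward the circle center by
    ``chord_pull``.
    """
    r = layout.radiusPx
    size = 2 * (r + marginPx)
    cx = cy = r + marginPx
    scene = SvgScene(size, size)

    def point(angle: float) -> tuple[float, float]:
        return (cx + r * math.cos(angle), cy + r * math.sin(angle))

    for region, a0, a1 in layout.entries:
        x0, y0 = point(a0)
        x1, y1 = point(a1)
        large = 1 if (a1 - a0) > math.pi else 0
        scene.add("arcs", "path", {
            "class": "chrom-arc",
            "d": f"M {_fmt(x0)} {_fmt(y0)} A {_fmt(r)} {_fmt(r)} 0 {large} 1 "
                 f"{_fmt(x1)} {_fmt(y1)}",
            "fill": "none", "stroke": "#444444", "stroke-width": 6,
        }, elem_id=f"arc-{region.refName}-{region.start}")
        mid = (a0 + a1) / 2
        lx = cx + (r + 12) * math.cos(mid)
        ly = cy + (r + 12) * math.sin(mid)
        scene.add("arcs", "text", {
            "class": "arc-label", "x": lx, "y": ly, "font-size": 9,
            "text-anchor": "middle",
        }, text=region.refName)

    for event in events:
        if event.end2 is None:
            log.info("event %s is single-ended; no chord", event.id)
            continue
        a1 = layout.bp_to_angle(*event.end1)
        a2 = layout.bp_to_angle(*event.end2)
        if a1 is None or a2 is None:
            log.warning("event %s touches an undisplayed sequence; skipped",
                        event.id)
            continue
        x1, y1 = point(a1)
        x2, y2 = point(a2)
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        qx = cx + (mx - cx) * chord_pull
        qy = cy + (my - cy) * chord_pull
        scene.add("chords", "path", {
            "class": f"chord chord-{event.kind}",
            "d": f"M {_fmt(x1)} {_fmt(y1)} Q {_fmt(qx)} {_fmt(qy)} "
                 f"{_fmt(x2)} {_fmt(y2)}",
            "fill": "none", "stroke": PALETTE["chord"],
        }, elem_id=f"chord-{event.id}")
    return scene


# ---------------------------------------------------------------------------
# dotplot view


def render_dotplot(
    blocks: Sequence[SyntenyBlock],
    qDisplayed: DisplayedRegions,
    tDisplayed: DisplayedRegions,
    widthPx: float = 600.0,
    heightPx: float = 600.0,
    marginPx: float = 40.0,
) -> SvgScene:
    """Dotplot: target on x, query on y with the origin at bottom-left."""
    plot_w = widthPx - 2 * marginPx
    plot_h = heightPx - 2 * marginPx
    if plot_w <= 0 or plot_h <= 0:
        raise RenderError("dotplot too small for its margins")
    bpp_t = tDisplayed.bp_per_px_for_width(plot_w)
    bpp_q = qDisplayed.bp_per_px_for_width(plot_h)
    scene = SvgScene(widthPx, heightPx)

    def x_of(name: str, coord: float) -> Optional[float]:
        px = tDisplayed.bp_to_px_edge(name, coord, bpp_t)
        return None if px is None else marginPx + px

    def y_of(name: str, coord: float) -> Optional[float]:
        px = qDisplayed.bp_to_px_edge(name, coord, bpp_q)
        return None if px is None else marginPx + plot_h - px

    scene.add("frame", "rect", {
        "class": "plot-frame", "x": marginPx, "y": marginPx,
        "width": plot_w, "height": plot_h, "fill": "none",
        "stroke": "#000000",
    })
    # gridlines at region boundaries
    acc = 0.0
    for i, region in enumerate(tDisplayed):
        if i > 0:
            x = marginPx + acc + tDisplayed.interRegionPadding / 2
            scene.add("grid", "line", {
                "class": "gridline gridline-x", "x1": x, "x2": x,
                "y1": marginPx, "y2": marginPx + plot_h, "stroke": "#dddddd",
            })
            acc += tDisplayed.interRegionPadding
        acc += region.length / bpp_t
    acc = 0.0
    for i, region in enumerate(qDisplayed):
        if i > 0:
            y = marginPx + plot_h - (acc + qDisplayed.interRegionPadding / 2)
            scene.add("grid", "line", {
                "class": "gridline gridline-y", "x1": marginPx,
                "x2": marginPx + plot_w, "y1": y, "y2": y, "stroke": "#dddddd",
            })
            acc += qDisplayed.interRegionPadding
        acc += region.length / bpp_q

    for bi, block in enumerate(blocks):
        points = []
        ok = True
        for t, q in dotplot_path(block):
            x = x_of(block.tName, t)
            y = y_of(block.qName, q)
            if x is None or y is None:
                ok = False
                break
            points.append((x, y))
        if not ok or not points:
            log.warning("block %s/%s outside the displayed axes; skipped",
                        block.qName, block.tName)
            continue
        d = "M " + " L ".join(f"{_fmt(x)} {_fmt(y)}" for x, y in points)
        scene.add("blocks", "path", {
            "class": f"synteny-block strand-{'plus' if block.strand == '+' else 'minus'}",
            "d": d, "fill": "none",
            "stroke": "#d62728" if block.strand == "-" else "#1f77b4",
        }, elem_id=f"blocks-{bi}")
    return scene


# ---------------------------------------------------------------------------
# linear synteny view


def render_synteny(
    topDisplayed: DisplayedRegions,
    bottomDisplayed: DisplayedRegions,
    blocks: Sequence[SyntenyBlock],
    detail: str = "ribbon",
    widthPx: float = 800.0,
    heightPx: float = 220.0,
) -> SvgScene:
    """Two stacked linear axes (target on top, query on bottom) joined by
    ribbons — one quadrilateral per block, corners crossed for '-' — or by
    per-match-segment polygons in ``cigar-level`` detail."""
    if detail not in ("ribbon", "cigar-level"):
        raise RenderError(f"unknown synteny detail {detail!r}")
    bpp_t = topDisplayed.bp_per_px_for_width(widthPx)
    bpp_q = bottomDisplayed.bp_per_px_for_width(widthPx)
    y_top, y_bot = 30.0, heightPx - 30.0
    scene = SvgScene(widthPx, heightPx)
    _draw_ruler(scene, "ruler-top", topDisplayed, bpp_t, 0.0)
    _draw_ruler(scene, "ruler-bottom", bottomDisplayed, bpp_q, y_bot + 2)

    def xt(name: str, coord: float) -> Optional[float]:
        return topDisplayed.bp_to_px_edge(name, coord, bpp_t)

    def xq(name: str, coord: float) -> Optional[float]:
        return bottomDisplayed.bp_to_px_edge(name, coord, bpp_q)

    def quad(eid: str, t0: float, t1: float, q0: float, q1: float,
             cls: str) -> None:
        points = (f"{_fmt(t0)},{_fmt(y_top)} {_fmt(t1)},{_fmt(y_top)} "
                  f"{_fmt(q1)},{_fmt(y_bot)} {_fmt(q0)},{_fmt(y_bot)}")
        scene.add("ribbons", "polygon", {
            "class": cls, "points": points,
            "fill": PALETTE["synteny"], "stroke": "none",
        }, elem_id=eid)

    for bi, block in enumerate(blocks):
        t0, t1 = xt(block.tName, block.tStart), xt(block.tName, block.tEnd)
        if t0 is None or t1 is None:
            log.warning("block %s/%s outside the top view; skipped",
                        block.qName, block.tName)
            continue
        if block.strand == "+":
            q0, q1 = xq(block.qName, block.qStart), xq(block.qName, block.qEnd)
        else:  # crossed: tStart joins qEnd
            q0, q1 = xq(block.qName, block.qEnd), xq(block.qName, block.qStart)
        if q0 is None or q1 is None:
            log.warning("block %s/%s outside the bottom view; skipped",
                        block.qName, block.tName)
            continue
        strand_cls = "plus" if block.strand == "+" else "minus"
        if detail == "ribbon" or block.cigar is None:
            quad(f"ribbon-{bi}", t0, t1, q0, q1,
                 f"synteny-ribbon strand-{strand_cls}")
            continue
        # cigar-level: one polygon per match run
        qdir = 1 if block.strand == "+" else -1
        q = block.qStart if block.strand == "+" else block.qEnd
        t = block.tStart
        seg = 0
        for op, n in block.cigar:
            if op in "M=X":
                tq0 = xq(block.qName, q)
                tq1 = xq(block.qName, q + qdir * n)
                quad(f"ribbon-{bi}-{seg}", xt(block.tName, t),
                     xt(block.tName, t + n), tq0, tq1,
                     f"synteny-segment strand-{strand_cls}")
                t += n
                q += qdir * n
                seg += 1
            elif op in "DN":
                t += n
            elif op == "I":
                q += qdir * n
    return scene


# ---------------------------------------------------------------------------
# breakpoint split view


def render_breakpoint_split(
    panelA: DisplayedRegions,
    panelB: Optional[DisplayedRegions],
    tracksA: Sequence[dict],
    tracksB: Sequence[dict],
    connectors: Sequence[Connector],
    event: SVEvent,
    widthPx: float = 800.0,
    panelHeightPx: float = 140.0,
    gapPx: float = 40.0,
) -> SvgScene:
    """Two stacked linear panels with split-read connectors and the variant.

    Each connector becomes one cubic curve between its two (panel, px)
    endpoints.  The variant call is a vertical line in the distinguished
    style with short perpendicular "feet" at each end pointing toward the
    retained side of the junction (left for ``left_of_pos``)."""
    panels = [panelA] + ([panelB] if panelB is not None else [])
    height = len(panels) * panelHeightPx + (len(panels) - 1) * gapPx
    scene = SvgScene(widthPx, height)
    bpps, y0s = [], []
    for pi, displayed in enumerate(panels):
        bpp = displayed.bp_per_px_for_width(widthPx)
        y0 = pi * (panelHeightPx + gapPx)
        bpps.append(bpp)
        y0s.append(y0)
        y = _draw_ruler(scene, f"panel{pi}-ruler", displayed, bpp, y0)
        tracks = tracksA if pi == 0 else tracksB
        for track in tracks:
            track = dict(track, trackId=f"p{pi}-{track['trackId']}")
            y = _draw_track(scene, displayed, bpp, track, y)

    def locate(end: tuple[int, str, int]) -> Optional[tuple[float, float, float]]:
        panel, ref, pos = end
        if panel >= len(panels):
            return None
        x = panels[panel].bp_to_px_edge(ref, pos, bpps[panel])
        if x is None:
            return None
        return (x, y0s[panel], y0s[panel] + panelHeightPx)

    for ci, conn in enumerate(connectors):
        a = locate(conn.endA)
        b = locate(conn.endB)
        if a is None or b is None:
            log.warning("connector for read %s outside panels; skipped",
                        conn.readName)
            continue
        (xa, a_top, a_bot), (xb, b_top, b_bot) = a, b
        if a_top == b_top:  # same panel: arc below the panel
            ya = yb = a_bot
            ca, cb = ya + 20, yb + 20
        elif a_top < b_top:
            ya, yb = a_bot, b_top
            ca, cb = ya + gapPx / 2, yb - gapPx / 2
        else:
            ya, yb = a_top, b_bot
            ca, cb = ya - gapPx / 2, yb + gapPx / 2
        scene.add("connectors", "path", {
            "class": "connector",
            "d": f"M {_fmt(xa)} {_fmt(ya)} C {_fmt(xa)} {_fmt(ca)} "
                 f"{_fmt(xb)} {_fmt(cb)} {_fmt(xb)} {_fmt(yb)}",
            "fill": "none", "stroke": PALETTE["connector"],
        }, elem_id=f"connector-{ci}-{conn.readName}")

    foot = 6.0
    ends = [(0, event.end1, event.joinSide1)]
    if event.end2 is not None and panelB is not None:
        ends.append((1, event.end2, event.joinSide2))
    for pi, (ref, pos), join_side in ends:
        x = panels[pi].bp_to_px_edge(ref, pos, bpps[pi])
        if x is None:
            log.warning("event end %s:%d outside panel %d", ref, pos, pi)
            continue
        y_a, y_b = y0s[pi] + 20, y0s[pi] + panelHeightPx
        scene.add("variant", "line", {
            "class": "variant-line", "x1": x, "x2": x, "y1": y_a, "y2": y_b,
            "stroke": PALETTE["variant_line"], "stroke-width": 2,
        }, elem_id=f"variant-line-{pi}")
        dx = -foot if join_side == LEFT_OF_POS else foot
        for tag, yy in (("top", y_a), ("bottom", y_b)):
            scene.add("variant", "line", {
                "class": "variant-foot", "x1": x, "x2": x + dx,
                "y1": yy, "y2": yy,
                "stroke": PALETTE["variant_line"], "stroke-width": 2,
            }, elem_id=f"variant-foot-{pi}-{tag}")
    return scene


# ---------------------------------------------------------------------------
# ideogram


def render_ideogram(
    assembly: Assembly,
    refName: str,
    highlight: Optional[Region] = None,
    widthPx: float = 400.0,
    heightPx: float = 16.0,
) -> SvgScene:
    """Chromosome overview: one rect per cytoband (stain as class), with the
    highlighted window drawn on top; plain ruler fallback without bands."""
    canonical = assembly.canonical(refName)
    length = assembly.seq_length(canonical)
    scale = widthPx / length
    scene = SvgScene(widthPx, heightPx)
    bands = assembly.bands_for(canonical)
    if bands:
        fills = {"gneg": "#ffffff", "gpos25": "#c0c0c0", "gpos50": "#808080",
                 "gpos75": "#404040", "gpos100": "#000000", "acen": "#cc3333",
                 "gvar": "#e0c0e0", "stalk": "#7f9fbf"}
        for band in bands:
            scene.add("bands", "rect", {
                "class": f"band {band.stain}",
                "x": band.start * scale, "y": 2,
                "width": (band.end - band.start) * scale,
                "height": heightPx - 4,
                "fill": fills.get(band.stain, "#aaaaaa"), "stroke": "#333333",
                "stroke-width": 0.25,
            }, elem_id=f"band-{band.name}")
    else:
        scene.add("ruler-fallback", "line", {
            "class": "baseline", "x1": 0, "x2": widthPx,
            "y1": heightPx / 2, "y2": heightPx / 2, "stroke": "#333333",
        })
        spacing = tick_spacing_bp(length)
        for coord in range(0, length, spacing):
            x = coord * scale
            scene.add("ruler-fallback", "line", {
                "class": "tick", "x1": x, "x2": x,
                "y1": heightPx / 2 - 3, "y2": heightPx / 2 + 3,
                "stroke": "#333333",
            })
    if highlight is not None and highlight.refName == canonical:
        scene.add("highlight", "rect", {
            "class": "highlight", "x": highlight.start * scale, "y": 0,
            "width": max((highlight.end - highlight.start) * scale, 1.0),
            "height": heightPx, "fill": "#ff000044", "stroke": "#ff0000",
        })
    return scene
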