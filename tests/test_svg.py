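"""Scene construction: determinism, coordinate agreement, view geometry."""

import math
import re
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from genoscene.errors import RenderError
from genoscene.features import Feature
from genoscene.genome import Assembly, Cytoband, DisplayedRegions, Region
from genoscene.sv import LEFT_OF_POS, RIGHT_OF_POS, Connector, SVEvent
from genoscene.svg import (CircleLayout, SvgScene, layout_circle,
                           render_breakpoint_split, render_circular,
                           render_dotplot, render_ideogram, render_linear,
                           render_synteny, tick_spacing_bp)
from genoscene.synteny import SyntenyBlock

SVGNS = "{http://www.w3.org/2000/svg}"


def _parse(svg_text):
    return ET.fromstring(svg_text)


def _by_class(root, cls):
    return [el for el in root.iter()
            if cls in el.attrib.get("class", "").split()]


class TestSvgScene:
    def test_serialization_is_byte_stable(self):
        def build():
            s = SvgScene(100, 50)
            s.add("g1", "rect", {"x": 1.23456, "y": 2, "class": "a"})
            s.add("g1", "line", {"x1": 0, "x2": 10.5, "y1": 0, "y2": 0})
            s.add("g2", "text", {"x": 5, "y": 5}, text="label")
            return s.to_svg()

        assert build() == build()
        _parse(build())  # well-formed XML

    def test_duplicate_ids_rejected(self):
        s = SvgScene(10, 10)
        s.add("g", "rect", {}, elem_id="e1")
        with pytest.raises(RenderError):
            s.add("g", "rect", {}, elem_id="e1")

    def test_non_finite_coordinates_rejected(self):
        s = SvgScene(10, 10)
        with pytest.raises(RenderError):
            s.add("g", "rect", {"x": float("nan")})


class TestRenderLinear:
    def test_no_tracks_gives_ruler_only(self):
        displayed = DisplayedRegions([Region("chr1", 0, 1000)], 0)
        scene = render_linear(displayed, [], widthPx=500)
        # tick policy: spacing = 100 for a 1000 bp view -> ticks at 0..900
        assert tick_spacing_bp(1000) == 100
        assert len(scene.elements("ruler", cls="tick")) == 10
        assert scene.elements("separators") == []

    def test_three_disjoint_features_three_rects(self):
        displayed = DisplayedRegions([Region("chr1", 0, 1000)], 0)
        feats = [Feature(f"f{i}", "chr1", 100 * i, 100 * i + 40, ".", "gene")
                 for i in range(3)]
        scene = render_linear(
            displayed, [{"trackId": "t", "type": "feature", "data": feats}],
            widthPx=500)
        assert len(scene.elements(cls="feature")) == 3

    def test_feature_x_equals_transform_of_start(self):
        displayed = DisplayedRegions(
            [Region("chr1", 0, 500), Region("chr2", 100, 600)], 2)
        feats = [Feature("f1", "chr2", 250, 300, "+", "gene")]
        scene = render_linear(
            displayed, [{"trackId": "t", "type": "feature", "data": feats}],
            bpPerPx=2.0)
        rect = scene.elements(cls="feature")[0]
        want = displayed.bp_to_px("chr2", 250, 2.0)
        assert rect["attrs"]["x"] == pytest.approx(want)

    def test_separator_per_region_boundary(self):
        displayed = DisplayedRegions(
            [Region("chr1", 0, 100), Region("chr2", 0, 100),
             Region("chr1", 0, 50)], 2)
        scene = render_linear(displayed, [], widthPx=400)
        assert len(scene.elements("separators", cls="separator")) == 2

    def test_zero_width_view_rejected(self):
        displayed = DisplayedRegions([Region("chr1", 0, 100)], 0)
        with pytest.raises(RenderError):
            render_linear(displayed, [], widthPx=0)

    def test_drawn_x_matches_transform_parsed_back_from_svg(self):
        displayed = DisplayedRegions([Region("chr1", 0, 2000)], 0)
        feats = [Feature(f"f{i}", "chr1", s, s + 25, ".", "gene")
                 for i, s in enumerate((3, 777, 1500))]
        scene = render_linear(
            displayed, [{"trackId": "t", "type": "feature", "data": feats}],
            bpPerPx=4.0)
        root = _parse(scene.to_svg())
        rects = sorted(_by_class(root, "feature"),
                       key=lambda el: float(el.attrib["x"]))
        for el, feat in zip(rects, feats):
            want = displayed.bp_to_px("chr1", feat.start, 4.0)
            assert float(el.attrib["x"]) == pytest.approx(want, abs=1e-3)


class TestCircleLayout:
    def test_two_equal_chromosomes_split_the_circle(self):
        layout = layout_circle([Region("c1", 0, 100), Region("c2", 0, 100)], 0)
        spans = [a1 - a0 for _, a0, a1 in layout.entries]
        assert spans == [pytest.approx(math.pi)] * 2

    def test_three_to_one_proportionality(self):
        layout = layout_circle([Region("c1", 0, 300), Region("c2", 0, 100)], 0)
        spans = [a1 - a0 for _, a0, a1 in layout.entries]
        assert spans[0] == pytest.approx(3 * math.pi / 2)
        assert spans[1] == pytest.approx(math.pi / 2)

    def test_conservation_on_random_assemblies(self):
        rng = np.random.default_rng(47)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            regions = [Region(f"c{i}", 0, int(rng.integers(1, 10**6)))
                       for i in range(n)]
            gap = float(rng.uniform(0, math.pi / (2 * n)))
            layout = layout_circle(regions, gapAngle=gap)
            total = sum(a1 - a0 for _, a0, a1 in layout.entries)
            assert abs(total - (2 * math.pi - n * gap)) < 1e-9


class TestRenderCircular:
    def _layout(self):
        return layout_circle([Region("chr1", 0, 1000), Region("chr2", 0, 1000)],
                             gapAngle=0.1, radiusPx=150)

    def test_chord_endpoints_on_inner_radius(self):
        layout = self._layout()
        events = [SVEvent(id=f"e{i}", kind="BND", end1=("chr1", 100 + i * 50),
                          end2=("chr2", 300 + i * 40)) for i in range(5)]
        scene = render_circular(layout, events)
        root = _parse(scene.to_svg())
        chords = _by_class(root, "chord")
        assert len(chords) == 5
        cx = cy = 150 + 30  # radius + default margin
        for el in chords:
            numbers = [float(x) for x in re.findall(r"-?\d+\.?\d*",
                                                    el.attrib["d"])]
            x1, y1, x2, y2 = numbers[0], numbers[1], numbers[-2], numbers[-1]
            for x, y in ((x1, y1), (x2, y2)):
                assert math.hypot(x - cx, y - cy) == pytest.approx(150, abs=0.5)

    def test_zero_events_gives_arcs_only(self):
        scene = render_circular(self._layout(), [])
        assert len(scene.elements(cls="chrom-arc")) == 2
        assert scene.elements(cls="chord") == []

    def test_event_on_undisplayed_sequence_skipped(self, caplog):
        import logging

        event = SVEvent(id="x", kind="BND", end1=("chrZ", 10),
                        end2=("chr1", 10))
        with caplog.at_level(logging.WARNING, logger="genoscene.svg"):
            scene = render_circular(self._layout(), [event])
        assert scene.elements(cls="chord") == []
        assert any("undisplayed" in r.message for r in caplog.records)


class TestRenderDotplot:
    def test_full_span_block_runs_corner_to_corner(self):
        q = DisplayedRegions([Region("q1", 0, 100)], 0)
        t = DisplayedRegions([Region("t1", 0, 200)], 0)
        block = SyntenyBlock("q1", 100, 0, 100, "+", "t1", 200, 0, 200)
        scene = render_dotplot([block], q, t, widthPx=280, heightPx=280,
                               marginPx=40)
        el = scene.elements(cls="synteny-block")[0]
        coords = [float(x) for x in re.findall(r"-?\d+\.?\d*", el["attrs"]["d"])]
        # target x: 40..240; query y inverted: bottom (240) to top (40)
        assert coords == [40, 240, 240, 40]

    def test_vertex_coordinates_equal_composed_transforms(self):
        q = DisplayedRegions([Region("q1", 0, 300)], 0)
        t = DisplayedRegions([Region("t1", 0, 400)], 0)
        block = SyntenyBlock("q1", 300, 50, 70, "-", "t1", 400, 100, 130,
                             cigar=[("M", 10), ("D", 10), ("M", 10)])
        width = height = 480
        margin = 40
        scene = render_dotplot([block], q, t, width, height, margin)
        el = scene.elements(cls="synteny-block")[0]
        got = [float(x) for x in re.findall(r"-?\d+\.?\d*", el["attrs"]["d"])]
        bpp_t = 400 / (width - 2 * margin)
        bpp_q = 300 / (height - 2 * margin)
        from genoscene.synteny import dotplot_path

        want = []
        for tv, qv in dotplot_path(block):
            want += [margin + tv / bpp_t,
                     margin + (height - 2 * margin) - qv / bpp_q]
        assert got == pytest.approx(want, abs=2e-3)


class TestRenderSynteny:
    def test_plus_block_quadrilateral_corners(self):
        top = DisplayedRegions([Region("t1", 0, 400)], 0)
        bottom = DisplayedRegions([Region("q1", 0, 400)], 0)
        block = SyntenyBlock("q1", 400, 100, 200, "+", "t1", 400, 50, 150)
        scene = render_synteny(top, bottom, [block], widthPx=400,
                               heightPx=220)
        el = scene.elements(cls="synteny-ribbon")[0]
        pts = [tuple(map(float, p.split(",")))
               for p in el["attrs"]["points"].split()]
        assert pts[0] == (50, 30) and pts[1] == (150, 30)
        assert pts[2] == (200, 190) and pts[3] == (100, 190)

    def test_minus_block_corners_crossed(self):
        top = DisplayedRegions([Region("t1", 0, 400)], 0)
        bottom = DisplayedRegions([Region("q1", 0, 400)], 0)
        block = SyntenyBlock("q1", 400, 100, 200, "-", "t1", 400, 50, 150)
        scene = render_synteny(top, bottom, [block], widthPx=400)
        el = scene.elements(cls="synteny-ribbon")[0]
        pts = [tuple(map(float, p.split(",")))
               for p in el["attrs"]["points"].split()]
        # tStart (x=50) joins qEnd (x=200)
        assert pts[0][0] == 50 and pts[3][0] == 200

    def test_block_outside_views_is_skipped(self):
        top = DisplayedRegions([Region("t1", 0, 400)], 0)
        bottom = DisplayedRegions([Region("q1", 0, 400)], 0)
        block = SyntenyBlock("qZ", 400, 0, 10, "+", "tZ", 400, 0, 10)
        scene = render_synteny(top, bottom, [block], widthPx=400)
        assert scene.elements(cls="synteny-ribbon") == []


class TestRenderBreakpointSplit:
    def _scene(self, join1=LEFT_OF_POS, join2=RIGHT_OF_POS, n_connectors=4):
        panel_a = DisplayedRegions([Region("chr1", 4000, 6000)], 0)
        panel_b = DisplayedRegions([Region("chr5", 6000, 8000)], 0)
        event = SVEvent(id="e", kind="BND", end1=("chr1", 5000),
                        end2=("chr5", 7000), joinSide1=join1, joinSide2=join2)
        connectors = [
            Connector(f"read{i}", (0, "chr1", 5000), (1, "chr5", 7000))
            for i in range(n_connectors)
        ]
        return render_breakpoint_split(panel_a, panel_b, [], [], connectors,
                                       event, widthPx=400)

    def test_connector_and_variant_line_counts(self):
        scene = self._scene(n_connectors=4)
        assert len(scene.elements(cls="connector")) == 4
        assert len(scene.elements(cls="variant-line")) == 2  # one per panel

    def test_no_connectors_still_draws_variant(self):
        scene = self._scene(n_connectors=0)
        assert scene.elements(cls="connector") == []
        assert len(scene.elements(cls="variant-line")) == 2

    def test_feet_direction_flips_with_join_side(self):
        def foot_dx(scene, panel):
            el = next(e for e in scene.elements(cls="variant-foot")
                      if e["id"] == f"variant-foot-{panel}-top")
            return el["attrs"]["x2"] - el["attrs"]["x1"]

        left = self._scene(join1=LEFT_OF_POS, join2=LEFT_OF_POS)
        right = self._scene(join1=RIGHT_OF_POS, join2=RIGHT_OF_POS)
        assert foot_dx(left, 0) < 0 < foot_dx(right, 0)
        assert foot_dx(left, 1) < 0 < foot_dx(right, 1)


class TestRenderIdeogram:
    def _assembly(self):
        bands = [Cytoband("chr1", 0, 300, "p11", "gneg"),
                 Cytoband("chr1", 300, 500, "cen", "acen"),
                 Cytoband("chr1", 500, 1000, "q11", "gpos50")]
        return Assembly("a", [("chr1", 1000)], cytobands=bands)

    def test_one_rect_per_band(self):
        scene = render_ideogram(self._assembly(), "chr1")
        assert len(scene.elements(cls="band")) == 3

    def test_band_widths_proportional_to_lengths(self):
        scene = render_ideogram(self._assembly(), "chr1", widthPx=500)
        widths = [el["attrs"]["width"] for el in scene.elements(cls="band")]
        assert widths == pytest.approx([150, 100, 250])

    def test_fallback_ruler_without_cytobands(self):
        assembly = Assembly("a", [("chr1", 1000)])
        scene = render_ideogram(assembly, "chr1")
        assert scene.elements(cls="band") == []
        assert scene.elements("ruler-fallback")


class TestDeterminism:
    def test_every_view_renders_byte_identically_twice(self, sv_demo,
                                                       sv_demo_assembly):
        from genoscene.cli import run_cli

        cfg = sv_demo["paths"]["config"]
        vcf = sv_demo["paths"]["truth_vcf"]
        import tempfile, os, filecmp

        with tempfile.TemporaryDirectory() as tmp:
            jobs = [
                ["render", "linear", "--config", cfg, "--loc",
                 "chr1:29,000-31,000", "--tracks", "genes,reads,svs"],
                ["render", "dotplot", "--config", cfg, "--track", "synteny"],
                ["render", "synteny", "--config", cfg, "--track", "synteny"],
                ["render", "circular", "--config", cfg, "--vcf", vcf],
                ["render", "breakpoint", "--config", cfg, "--vcf", vcf,
                 "--alignments", "reads"],
            ]
            for i, job in enumerate(jobs):
                out1 = os.path.join(tmp, f"a{i}.svg")
                out2 = os.path.join(tmp, f"b{i}.svg")
                assert run_cli(job + ["--out", out1]) == 0
                assert run_cli(job + ["--out", out2]) == 0
                assert open(out1).read() == open(out2).read(), job[1]
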