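"""Value-to-color mapping, overlays, and the color-bar legend."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netglyph import (
    BoundingBox,
    ColorMap,
    OverlaySpec,
    Point,
    add_color_bar,
    apply_overlay,
    apply_default_template,
    generate_layout,
    parse_model,
    read_sbml,
    resolve_style,
    value_to_color,
    write_sbml,
)
from netglyph.errors import LayoutError

BW = ColorMap([(0.0, "#000000"), (1.0, "#FFFFFF")], name="bw")


def test_endpoint_colors_exact():
    cmap = ColorMap()
    assert value_to_color(0.0, 0.0, 10.0, cmap) == "#C8C8C8"
    assert value_to_color(10.0, 0.0, 10.0, cmap) == "#FF4500"
    assert value_to_color(-5.0, 0.0, 10.0, cmap) == "#C8C8C8"  # clamped


def test_black_white_midpoint_rounds_half_up():
    assert value_to_color(5.0, 0.0, 10.0, BW) == "#808080"  # 127.5 -> 128


@settings(deadline=None, max_examples=50)
@given(
    v1=st.floats(0, 10, allow_nan=False),
    v2=st.floats(0, 10, allow_nan=False),
)
def test_channel_monotonicity(v1, v2):
    cmap = ColorMap([(0.0, "#102030"), (0.5, "#5090B0"), (1.0, "#FFFFFF")])
    lo, hi = sorted((v1, v2))
    c_lo = value_to_color(lo, 0.0, 10.0, cmap)
    c_hi = value_to_color(hi, 0.0, 10.0, cmap)
    for i in (1, 3, 5):
        assert int(c_lo[i : i + 2], 16) <= int(c_hi[i : i + 2], 16)


@pytest.fixture()
def two_reaction_scene():
    lay = generate_layout(parse_model("A1: X -> Y;\nB1: Y -> Z;"), (400, 400))
    return lay, apply_default_template(lay)


def test_color_overlay_endpoints(two_reaction_scene):
    lay, render = two_reaction_scene
    spec = OverlaySpec(values={"A1": 0.0, "B1": 10.0}, mode="color")
    apply_overlay(lay, render, spec)
    a = resolve_style(render, lay.get_reaction_glyph("A1"))
    b = resolve_style(render, lay.get_reaction_glyph("B1"))
    assert a.stroke == spec.colormap.stops[0][1]
    assert b.stroke == spec.colormap.stops[-1][1]


def test_equal_values_map_to_midpoint(two_reaction_scene):
    lay, render = two_reaction_scene
    apply_overlay(lay, render, OverlaySpec(values={"A1": 3.0, "B1": 3.0}, mode="color"))
    mid = value_to_color(0.5, 0.0, 1.0, ColorMap())
    for rid in ("A1", "B1"):
        assert resolve_style(render, lay.get_reaction_glyph(rid)).stroke == mid


def test_size_overlay_hits_range_bounds(two_reaction_scene):
    lay, render = two_reaction_scene
    spec = OverlaySpec(values={"A1": 0.0, "B1": 10.0}, mode="size", size_range=(4, 40))
    apply_overlay(lay, render, spec)
    assert resolve_style(render, lay.get_reaction_glyph("A1")).stroke_width == 4
    assert resolve_style(render, lay.get_reaction_glyph("B1")).stroke_width == 40


def test_species_size_overlay_scales_about_center(two_reaction_scene):
    lay, render = two_reaction_scene
    g = lay.species_glyphs_of("X")[0]
    before = g.bounding_box.center
    aspect = g.bounding_box.height / g.bounding_box.width
    apply_overlay(
        lay, render,
        OverlaySpec(values={"X": 10.0}, mode="size", vmin=0, vmax=10, size_range=(20, 120)),
    )
    assert g.bounding_box.width == 120
    assert g.bounding_box.height == pytest.approx(120 * aspect)
    assert g.bounding_box.center == before


def test_unknown_overlay_id_rejected(two_reaction_scene):
    lay, render = two_reaction_scene
    with pytest.raises(LayoutError, match="ghost"):
        apply_overlay(lay, render, OverlaySpec(values={"ghost": 1.0}))


def test_overlay_idempotent_and_topology_preserving(two_reaction_scene):
    lay, render = two_reaction_scene
    spec = OverlaySpec(values={"A1": 1.0, "B1": 9.0}, mode="color")
    apply_overlay(lay, render, spec)
    lay2, render2 = copy.deepcopy(lay), copy.deepcopy(render)
    apply_overlay(lay2, render2, spec)
    assert lay2 == lay and render2 == render


def test_color_bar_structure(two_reaction_scene):
    lay, render = two_reaction_scene
    box = BoundingBox(Point(350, 50), 20, 200)
    add_color_bar(lay, render, ColorMap(), 0.0, 10.0, 2, box)
    segs = [g for g in lay.graphical_objects if g.id.startswith("colorbar_seg")]
    ticks = [t for t in lay.text_glyphs if t.id.startswith("colorbar_tick")]
    assert len(segs) == 32
    assert [t.text for t in ticks] == ["10", "0"]  # vmax top, vmin bottom
    assert ticks[0].bounding_box.center.y < ticks[1].bounding_box.center.y
    # re-adding replaces, not duplicates
    add_color_bar(lay, render, ColorMap(), 0.0, 10.0, 2, box)
    assert len([g for g in lay.graphical_objects if g.id.startswith("colorbar_")]) == 32


def test_color_bar_survives_sbml_round_trip(two_reaction_scene):
    lay, render = two_reaction_scene
    net = parse_model("A1: X -> Y;\nB1: Y -> Z;")
    add_color_bar(lay, render, ColorMap(), 0.0, 1.0, 3, BoundingBox(Point(350, 50), 20, 200))
    _, lay2, _ = read_sbml(write_sbml(net, lay, render))
    assert {g.id for g in lay.graphical_objects} == {g.id for g in lay2.graphical_objects}


def test_degenerate_color_bar_box_rejected(two_reaction_scene):
    lay, render = two_reaction_scene
    with pytest.raises(LayoutError):
        add_color_bar(lay, render, ColorMap(), 0, 1, 2, BoundingBox(Point(0, 0), 0, 100))
    with pytest.raises(LayoutError):
        add_color_bar(lay, render, ColorMap(), 0, 1, 1, BoundingBox(Point(0, 0), 10, 100))
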