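"""Circular/axial arrangement operators, main-participant selection, labels."""

import copy
import math

import pytest

from netglyph import (
    AxisSpec,
    CircleSpec,
    Point,
    align_axis,
    align_circle,
    align_label,
    generate_layout,
    parse_model,
)
from netglyph.arrange import recover_angle, select_main_participant
from netglyph.errors import LayoutError

CIRCLE_IDS = ["J2", "J3", "J4", "J5", "J6", "J7", "J8", "J9"]
CENTER = Point(2200, 2800)


def test_tca_circle_distances_and_angles(tca_handle):
    lay = tca_handle.layout
    expected_angles = [105.0 - 45.0 * i for i in range(8)]
    for rid, expected in zip(CIRCLE_IDS, expected_angles):
        c = lay.get_reaction_glyph(rid).center
        assert abs(c.distance(CENTER) - 1500.0) < 1e-6
        got = recover_angle(CENTER, c)
        assert abs((got - expected + 180) % 360 - 180) < 1e-6


def test_angular_order_matches_reaction_order(tca_handle):
    """Placed angular order equals the requested reaction order (unwrapped
    along the negative step)."""
    lay = tca_handle.layout
    angles = [recover_angle(CENTER, lay.get_reaction_glyph(r).center) for r in CIRCLE_IDS]
    unwrapped = [angles[0]]
    for a in angles[1:]:
        while a > unwrapped[-1]:
            a -= 360
        unwrapped.append(a)
    steps = [b - a for a, b in zip(unwrapped, unwrapped[1:])]
    assert all(abs(s + 45.0) < 1e-6 for s in steps)


def test_single_reaction_full_circle_at_arc_start():
    lay = generate_layout(parse_model("R1: A -> B;"), (400, 400))
    align_circle(lay, ["R1"], CircleSpec(Point(0, 0), 100, 0, 360))
    c = lay.get_reaction_glyph("R1").center
    assert c.distance(Point(100, 0)) < 1e-9


def test_inverse_trig_oracle_on_partial_arc():
    """Recomputing angles from placed centers reproduces arc_start + i*step
    (inclusive spacing on a partial arc)."""
    text = "".join(f"R{i}: A{i} -> B{i};\n" for i in range(5))
    lay = generate_layout(parse_model(text), (1000, 1000))
    spec = CircleSpec(Point(500, 500), 200, 30, 150)
    align_circle(lay, [f"R{i}" for i in range(5)], spec)
    step = (150 - 30) / 4
    for i in range(5):
        c = lay.get_reaction_glyph(f"R{i}").center
        assert abs(c.distance(spec.center) - 200) < 1e-6
        assert abs(recover_angle(spec.center, c) - (30 + i * step)) < 1e-6


def test_unknown_reaction_rejected():
    lay = generate_layout(parse_model("R1: A -> B;"), (400, 400))
    with pytest.raises(LayoutError):
        align_circle(lay, ["nope"], CircleSpec(Point(0, 0), 100, 0, 360))


def test_circle_idempotent(tca_handle):
    lay = tca_handle.layout
    before = copy.deepcopy(lay)
    align_circle(lay, CIRCLE_IDS, CircleSpec(CENTER, 1500, 105, -255))
    assert lay == before


def test_arrangement_preserves_topology(tca_handle):
    lay = tca_handle.layout
    counts = (
        len(lay.species_glyphs),
        len(lay.reaction_glyphs),
        len(lay.text_glyphs),
        [len(r.species_reference_glyphs) for r in lay.reaction_glyphs],
    )
    align_circle(lay, CIRCLE_IDS, CircleSpec(Point(100, 100), 50, 0, 360))
    assert counts == (
        len(lay.species_glyphs),
        len(lay.reaction_glyphs),
        len(lay.text_glyphs),
        [len(r.species_reference_glyphs) for r in lay.reaction_glyphs],
    )


# --- axial alignment -------------------------------------------------------


def test_j1_vertical_span(tca_handle):
    lay = tca_handle.layout
    sub = select_main_participant(lay, "J1", "substrate")
    prod = select_main_participant(lay, "J1", "product")
    assert sub.species_id == "Pyr" and prod.species_id == "AcCoA"
    cs, cp = sub.bounding_box.center, prod.bounding_box.center
    assert abs(cs.x - 2200) < 1e-6 and abs(cp.x - 2200) < 1e-6
    assert abs((cp.y - cs.y) - 800.0) < 1e-6
    assert abs(lay.get_reaction_glyph("J1").center.distance(Point(2200, 700))) < 1e-6


def test_horizontal_mirror():
    lay = generate_layout(parse_model("R1: A -> B;"), (400, 400))
    align_axis(lay, "R1", AxisSpec("horizontal", Point(0, 0), 100))
    a = lay.get_species_glyph("A_glyph").bounding_box.center
    b = lay.get_species_glyph("B_glyph").bounding_box.center
    assert (a.x, a.y) == (-50.0, 0.0)
    assert (b.x, b.y) == (50.0, 0.0)


def test_zero_spread_rejected():
    with pytest.raises(ValueError):
        AxisSpec("vertical", Point(0, 0), 0)


def test_axis_idempotent(tca_handle):
    lay = tca_handle.layout
    before = copy.deepcopy(lay)
    align_axis(lay, "J1", AxisSpec("vertical", Point(2200, 700), 800))
    assert lay == before


# --- main-participant selection --------------------------------------------


def test_main_selection_by_degree_then_declaration(tca_handle):
    lay = tca_handle.layout
    # AcCoA (degree 2: J1 product, J2 substrate) beats CO2 (degree 1 after aliasing)
    assert select_main_participant(lay, "J1", "product").species_id == "AcCoA"
    # all three J1 reactants tie at degree 1; Pyr is declared first
    assert select_main_participant(lay, "J1", "substrate").species_id == "Pyr"


def test_main_selection_single_candidate():
    lay = generate_layout(parse_model("R1: A -> B;"), (400, 400))
    assert select_main_participant(lay, "R1", "substrate").species_id == "A"
    with pytest.raises(LayoutError):
        lay2 = generate_layout(parse_model(""), (10, 10))
        select_main_participant(lay2, "R1", "substrate")


# --- label alignment -------------------------------------------------------


@pytest.mark.parametrize(
    "mode, expect",
    [("vertical_center", (5.0, 40.0)), ("top", (5.0, 0.0)), ("bottom", (5.0, 80.0))],
)
def test_label_alignment_modes(mode, expect):
    from netglyph.layout import BoundingBox, Layout, SpeciesGlyph, TextGlyph

    lay = Layout(width=200, height=200)
    lay.species_glyphs.append(
        SpeciesGlyph("g", None, BoundingBox(Point(0, 0), 100, 100))
    )
    lay.text_glyphs.append(TextGlyph("t", "g", "x", BoundingBox(Point(5, 5), 30, 20)))
    align_label(lay, "g", mode)
    b = lay.text_glyphs[0].bounding_box
    assert (b.position.x, b.position.y) == expect
    align_label(lay, "g", mode)  # idempotent
    assert (b.position.x, b.position.y) == expect


def test_label_alignment_requires_label(tca_handle):
    # reaction glyphs carry no text glyph by default
    with pytest.raises(LayoutError):
        align_label(tca_handle.layout, "J1_glyph", "top")
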