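"""Force-directed placement properties and Bézier curve routing."""

import copy
import math

import numpy as np
import pytest

from netglyph import (
    AutoLayoutParams,
    force_directed_layout,
    generate_layout,
    parse_model,
    route_reaction_curves,
    tca_fixture,
)
from netglyph.autolayout import displacement_history
from netglyph.errors import LayoutError
from netglyph.layout import BoundingBox, Point
from netglyph.model import Network, Participant, Reaction, Species


def _centers(layout):
    return [
        (g.id, g.bounding_box.center.x, g.bounding_box.center.y)
        for g in layout.all_glyphs()
    ]


def two_node_layout(canvas=4000.0):
    """One species + one reaction glyph joined by a single edge."""
    net = Network(
        [Species("A", "A", "c")],
        [Reaction("R1", [Participant("A", "reactant")])],
        [("c", "c")],
    )
    return generate_layout(net, (canvas, canvas))


def test_single_node_feels_no_forces():
    net = Network([Species("A", "A", "c")], [], [("c", "c")])
    lay = generate_layout(net, (1000, 1000))
    params = AutoLayoutParams(seed=9)
    force_directed_layout(lay, params)
    # must equal the seeded initial draw: no forces ever apply
    rng = np.random.default_rng(9)
    x = rng.uniform(params.padding, 1000 - params.padding)
    y = rng.uniform(params.padding, 1000 - params.padding)
    c = lay.species_glyphs[0].bounding_box.center
    assert (c.x, c.y) == (x, y)


def test_two_node_equilibrium_distance_near_k():
    """Equilibrium of k^2/d repulsion vs d^2/k attraction is d = k."""
    lay = two_node_layout()
    force_directed_layout(lay, AutoLayoutParams(seed=3, iterations=800))
    a = lay.species_glyphs[0].bounding_box.center
    b = lay.reaction_glyphs[0].bounding_box.center
    k = math.sqrt(4000 * 4000 / 2)
    assert abs(a.distance(b) - k) / k < 0.05


def test_three_node_path_is_nearly_collinear():
    lay = generate_layout(parse_model("R1: A -> B;"), (4000, 4000))
    force_directed_layout(lay, AutoLayoutParams(seed=5, iterations=800))
    a = lay.get_species_glyph("A_glyph").bounding_box.center
    mid = lay.get_reaction_glyph("R1").bounding_box.center
    b = lay.get_species_glyph("B_glyph").bounding_box.center
    k = math.sqrt(4000 * 4000 / 3)
    u = np.array([b.x - a.x, b.y - a.y])
    u = u / np.linalg.norm(u)
    v = np.array([mid.x - a.x, mid.y - a.y])
    defect = abs(u[0] * v[1] - u[1] * v[0])
    assert defect < 0.05 * k


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_determinism_containment_energy_decrease(seed):
    net = tca_fixture()
    canvas = (4500, 5000)
    params = AutoLayoutParams(seed=seed)

    lay1 = force_directed_layout(generate_layout(net, canvas), params)
    lay2 = force_directed_layout(generate_layout(net, canvas), params)
    assert _centers(lay1) == _centers(lay2)  # bit-for-bit

    pad = params.padding
    for g in lay1.species_glyphs + lay1.reaction_glyphs:
        c = g.bounding_box.center
        assert pad <= c.x <= 4500 - pad and pad <= c.y <= 5000 - pad

    hist = displacement_history(generate_layout(net, canvas), params)
    assert hist[-1] <= hist[0]


def test_tca_min_pairwise_distance_regression():
    """Pinned once: seed-42 layout keeps all node centers >= 20 units apart."""
    lay = force_directed_layout(
        generate_layout(tca_fixture(), (4500, 5000)), AutoLayoutParams(seed=42)
    )
    centers = [g.bounding_box.center for g in lay.species_glyphs + lay.reaction_glyphs]
    dmin = min(
        centers[i].distance(centers[j])
        for i in range(len(centers))
        for j in range(i + 1, len(centers))
    )
    assert dmin >= 20


def test_zero_area_canvas_rejected():
    lay = two_node_layout()
    lay.width = 0
    with pytest.raises(LayoutError):
        force_directed_layout(lay, AutoLayoutParams(seed=1))


# --- routing ---------------------------------------------------------------


def test_collinear_reaction_routes_on_the_line():
    lay = generate_layout(parse_model("R1: A -> B;"), (400, 200))
    lay.move_glyph_center("A_glyph", Point(0, 50))
    lay.move_glyph_center("B_glyph", Point(200, 50))
    lay.move_glyph_center("R1_glyph", Point(100, 50))
    route_reaction_curves(lay)
    for srg in lay.get_reaction_glyph("R1").species_reference_glyphs:
        (seg,) = srg.curve
        for p in (seg.start, seg.end, seg.base_point1, seg.base_point2):
            assert p.y == 50


def test_curve_start_is_boundary_anchor(tca_handle):
    from netglyph.layout import glyph_boundary_anchor

    lay = tca_handle.layout
    for rg in lay.reaction_glyphs:
        for srg in rg.species_reference_glyphs:
            if srg.role not in ("substrate", "sidesubstrate"):
                continue
            sg = lay.get_species_glyph(srg.species_glyph_id)
            expected = glyph_boundary_anchor(sg.bounding_box, rg.center)
            assert srg.curve[0].start.distance(expected) < 1e-9


def _distance_to_box_border(p: Point, box: BoundingBox) -> float:
    x0, y0 = box.position.x, box.position.y
    x1, y1 = x0 + box.width, y0 + box.height
    if x0 <= p.x <= x1 and y0 <= p.y <= y1:
        return min(p.x - x0, x1 - p.x, p.y - y0, y1 - p.y)
    dx = max(x0 - p.x, 0, p.x - x1)
    dy = max(y0 - p.y, 0, p.y - y1)
    return math.hypot(dx, dy)


def test_tca_curve_endpoints_on_species_boundaries(tca_handle):
    """After the full worked-example arrangement every curve endpoint touches
    its species glyph's bounding box."""
    lay = tca_handle.layout
    n_checked = 0
    for rg in lay.reaction_glyphs:
        for srg in rg.species_reference_glyphs:
            sg = lay.get_species_glyph(srg.species_glyph_id)
            endpoint = (
                srg.curve[0].start
                if srg.role in ("substrate", "sidesubstrate", "modifier")
                else srg.curve[-1].end
            )
            assert _distance_to_box_border(endpoint, sg.bounding_box) < 1e-6
            n_checked += 1
    assert n_checked == sum(len(r.participants) for r in tca_handle.network.reactions)


def test_routing_requires_positions():
    lay = generate_layout(parse_model("R1: A -> B;"), (400, 200))
    lay.get_species_glyph("A_glyph").bounding_box.position = Point(math.nan, 0)
    with pytest.raises(LayoutError, match="A_glyph"):
        route_reaction_curves(lay)


def test_routing_deterministic(tca_handle):
    lay = copy.deepcopy(tca_handle.layout)
    route_reaction_curves(lay, ["J1"])
    again = copy.deepcopy(lay)
    route_reaction_curves(again, ["J1"])
    assert lay == again
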