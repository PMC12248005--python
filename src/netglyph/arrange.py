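"""Deterministic geometric arrangement: circular and axial alignment of
reactions, and label alignment.

Angles are in degrees and measured in the mathematical (counter-clockwise)
sense mapped into the y-down canvas frame:

    x = cx + r * cos(theta),   y = cy - r * sin(theta)

so theta = 90 is "up" on screen.  All placement is absolute (computed from the
arrangement spec alone), which makes every operator idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .autolayout import reroute_references_to, route_reaction_curves
from .errors import LayoutError
from .layout import (
    Layout,
    Point,
    ReactionGlyph,
    SpeciesGlyph,
    cubic,
    glyph_boundary_anchor,
)

# artifact constants for side-species placement, overridable per call
MAIN_ENDPOINT_FRAC = 0.4  # on-arc offset of main endpoints, as a fraction of the step
SIDE_RADIAL_FRAC = 0.18  # radial offset of side species, as a fraction of the radius
SIDE_LATERAL_FRAC = 0.35  # lateral offset of side species, as a fraction of the spread


@dataclass
class CircleSpec:
    center: Point
    radius: float
    arc_start_deg: float
    arc_end_deg: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.arc_start_deg == self.arc_end_deg:
            raise ValueError("arc must span a nonzero angle")


@dataclass
class AxisSpec:
    axis: str  # "vertical" | "horizontal"
    center: Point
    spread: float

    def __post_init__(self):
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError("axis must be 'vertical' or 'horizontal'")
        if self.spread <= 0:
            raise ValueError("spread must be > 0")


def _on_circle(spec: CircleSpec, theta_deg: float) -> Point:
    t = math.radians(theta_deg)
    return Point(
        spec.center.x + spec.radius * math.cos(t),
        spec.center.y - spec.radius * math.sin(t),
    )


def select_main_participant(layout: Layout, reaction_id: str, role: str) -> SpeciesGlyph:
    """The participant glyph carrying a role that best anchors the arrangement.

    Chosen by connection degree on the glyph graph (how many species-reference
    glyphs across all reactions point at the glyph) — a shared backbone
    metabolite beats a cofactor whose other uses have been aliased away.  Ties
    break by participant declaration order.
    """
    rg = layout.get_reaction_glyph(reaction_id)
    role_set = {role, "side" + role}
    candidates = [s for s in rg.species_reference_glyphs if s.role in role_set]
    if not candidates:
        raise LayoutError(f"reaction {reaction_id!r} has no participant of role {role!r}")
    best = max(candidates, key=lambda s: layout.glyph_degree(s.species_glyph_id))
    # max() keeps the first maximum, which is declaration order
    return layout.get_species_glyph(best.species_glyph_id)


def _side_glyphs(layout: Layout, rg: ReactionGlyph, role: str, exclude: set[str]) -> list[SpeciesGlyph]:
    """Glyphs of the given role, excluding ``exclude``, that are exclusive to
    this reaction (degree 1) and hence safe to move."""
    role_set = {role, "side" + role}
    out = []
    for srg in rg.species_reference_glyphs:
        if srg.role not in role_set or srg.species_glyph_id in exclude:
            continue
        if layout.glyph_degree(srg.species_glyph_id) == 1:
            out.append(layout.get_species_glyph(srg.species_glyph_id))
    return out


def align_circle(
    layout: Layout,
    reaction_ids: list[str],
    spec: CircleSpec,
    *,
    endpoint_frac: float = MAIN_ENDPOINT_FRAC,
    side_radial_frac: float = SIDE_RADIAL_FRAC,
) -> Layout:
    """Place reactions on a circle/arc in the order given.

    With n reactions spanning ``arc_end - arc_start``, the angular step is
    span/n for a full 360-degree span (endpoint-exclusive) and span/(n-1)
    otherwise; reaction i sits at ``arc_start + i*step``.  Each reaction's
    main substrate and product are placed on the circle at ``-/+
    endpoint_frac*step`` around the reaction; its exclusive side species go
    radially inside (substrates) or outside (products).  Curves are re-routed,
    with the main-chord base points kept on the circle so the curve bends
    along the arc.
    """
    n = len(reaction_ids)
    if n < 1:
        raise LayoutError("align_circle needs at least one reaction")
    for rid in reaction_ids:
        layout.get_reaction_glyph(rid)  # raises for unknown ids

    span = spec.arc_end_deg - spec.arc_start_deg
    if n == 1:
        step = 0.0
    elif abs(span) == 360.0:
        step = span / n  # full circle: endpoint-exclusive
    else:
        step = span / (n - 1)

    main_arcs: list[tuple[ReactionGlyph, float, str, str]] = []
    moved: set[str] = set()
    for i, rid in enumerate(reaction_ids):
        theta = spec.arc_start_deg + i * step
        rg = layout.get_reaction_glyph(rid)
        layout.move_glyph_center(rg.id, _on_circle(spec, theta))

        main_sub = select_main_participant(layout, rid, "substrate")
        main_prod = select_main_participant(layout, rid, "product")
        d = endpoint_frac * (step if step != 0.0 else 90.0)
        theta_sub, theta_prod = theta - d, theta + d
        layout.move_glyph_center(main_sub.id, _on_circle(spec, theta_sub))
        layout.move_glyph_center(main_prod.id, _on_circle(spec, theta_prod))
        main_arcs.append((rg, theta, main_sub.id, main_prod.id))
        moved.update({main_sub.id, main_prod.id})

        off = side_radial_frac * spec.radius
        exclude = {main_sub.id, main_prod.id}
        for role, radius in (("substrate", spec.radius - off), ("product", spec.radius + off)):
            sides = _side_glyphs(layout, rg, role, exclude)
            m = len(sides)
            sign = -1.0 if role == "substrate" else 1.0
            for k, g in enumerate(sides):
                frac = (k + 1) / (m + 1)
                ang = theta + sign * d * frac if step != 0.0 else theta + sign * 45.0 * frac
                c = Point(
                    spec.center.x + radius * math.cos(math.radians(ang)),
                    spec.center.y - radius * math.sin(math.radians(ang)),
                )
                layout.move_glyph_center(g.id, c)
                moved.add(g.id)

    route_reaction_curves(layout, reaction_ids)
    for rg, theta, sub_id, prod_id in main_arcs:
        _route_main_on_circle(layout, rg, spec, theta, sub_id, prod_id, endpoint_frac, step)
    reroute_references_to(layout, moved, set(reaction_ids))
    return layout


def _route_main_on_circle(layout, rg, spec, theta, sub_id, prod_id, endpoint_frac, step):
    """Replace the main substrate/product curves with arcs whose base points
    lie on the circle, so the chord bends along the arc."""
    d = endpoint_frac * (step if step != 0.0 else 90.0)
    center = rg.center
    for srg in rg.species_reference_glyphs:
        if srg.species_glyph_id == sub_id and srg.role in ("substrate", "sidesubstrate"):
            sg = layout.get_species_glyph(sub_id)
            start = glyph_boundary_anchor(sg.bounding_box, center)
            t0, t1 = theta - d, theta
            bp1 = _on_circle(spec, t0 + (t1 - t0) / 3)
            bp2 = _on_circle(spec, t0 + 2 * (t1 - t0) / 3)
            srg.curve = [cubic(start, center, bp1, bp2)]
            layout.custom_curves.add(srg.id)
        elif srg.species_glyph_id == prod_id and srg.role in ("product", "sideproduct"):
            sg = layout.get_species_glyph(prod_id)
            end = glyph_boundary_anchor(sg.bounding_box, center)
            t0, t1 = theta, theta + d
            bp1 = _on_circle(spec, t0 + (t1 - t0) / 3)
            bp2 = _on_circle(spec, t0 + 2 * (t1 - t0) / 3)
            srg.curve = [cubic(center, end, bp1, bp2)]
            layout.custom_curves.add(srg.id)


def align_axis(
    layout: Layout,
    reaction_id: str,
    spec: AxisSpec,
    *,
    side_lateral_frac: float = SIDE_LATERAL_FRAC,
) -> Layout:
    """Stretch one reaction along a vertical or horizontal axis.

    Vertical: reaction center at ``spec.center``; main substrate ``spread/2``
    above it, main product ``spread/2`` below; exclusive side substrates to
    the left and side products to the right, interpolated along the axis.
    Horizontal is the 90-degree-rotated mirror (substrate left, product
    right).
    """
    rg = layout.get_reaction_glyph(reaction_id)
    c, s = spec.center, spec.spread
    layout.move_glyph_center(rg.id, c)

    main_sub = select_main_participant(layout, reaction_id, "substrate")
    main_prod = select_main_participant(layout, reaction_id, "product")
    if spec.axis == "vertical":
        sub_c = Point(c.x, c.y - s / 2)
        prod_c = Point(c.x, c.y + s / 2)
    else:
        sub_c = Point(c.x - s / 2, c.y)
        prod_c = Point(c.x + s / 2, c.y)
    layout.move_glyph_center(main_sub.id, sub_c)
    layout.move_glyph_center(main_prod.id, prod_c)

    exclude = {main_sub.id, main_prod.id}
    moved = {main_sub.id, main_prod.id}
    lat = side_lateral_frac * s
    for role, sign in (("substrate", -1.0), ("product", +1.0)):
        sides = _side_glyphs(layout, rg, role, exclude)
        m = len(sides)
        for k, g in enumerate(sides):
            frac = (k + 1) / (m + 1)
            if spec.axis == "vertical":
                pos = Point(c.x + sign * lat, sub_c.y + frac * (prod_c.y - sub_c.y))
            else:
                pos = Point(sub_c.x + frac * (prod_c.x - sub_c.x), c.y + sign * lat)
            layout.move_glyph_center(g.id, pos)
            moved.add(g.id)

    route_reaction_curves(layout, [reaction_id])
    reroute_references_to(layout, moved, {reaction_id})
    return layout


LABEL_MODES = ("vertical_center", "horizontal_center", "top", "bottom", "left", "right")


def align_label(layout: Layout, target_glyph_id: str, mode: str) -> Layout:
    """Reposition the label(s) of a glyph relative to the glyph's box."""
    if mode not in LABEL_MODES:
        raise LayoutError(f"unknown label mode {mode!r}; expected one of {LABEL_MODES}")
    target = layout.get_glyph(target_glyph_id)
    labels = layout.text_glyphs_of(target_glyph_id)
    if not labels:
        raise LayoutError(f"glyph {target_glyph_id!r} has no label")
    tb = target.bounding_box
    for t in labels:
        b = t.bounding_box
        x, y = b.position.x, b.position.y
        if mode == "vertical_center":
            y = tb.position.y + (tb.height - b.height) / 2
        elif mode == "horizontal_center":
            x = tb.position.x + (tb.width - b.width) / 2
        elif mode == "top":
            y = tb.position.y
        elif mode == "bottom":
            y = tb.position.y + tb.height - b.height
        elif mode == "left":
            x = tb.position.x
        elif mode == "right":
            x = tb.position.x + tb.width - b.width
        b.position = Point(x, y)
    return layout


def recover_angle(spec_center: Point, placed: Point) -> float:
    """Inverse of the placement trigonometry: angle (degrees, in the module's
    y-down convention) of a placed point about a circle center."""
    return math.degrees(math.atan2(spec_center.y - placed.y, placed.x - spec_center.x))
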