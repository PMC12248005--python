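"""Deterministic SVG 1.1 export.

Glyphs are painted back-to-front — compartments, reaction curves, species
nodes, text, color-bar rectangles — with resolved render attributes mapped
1:1 onto SVG presentation attributes.  The writer is a plain string builder
with canonical number formatting, so identical in-memory state yields
byte-identical SVG.
"""

from __future__ import annotations

import math
from xml.sax.saxutils import escape, quoteattr

from .errors import LayoutError
from .layout import BoundingBox, CurveSegment, Layout
from .style import (
    CurvePrimitive,
    Ellipse,
    LineEnding,
    Polygon,
    Rectangle,
    RenderGroup,
    RenderInformation,
    resolve_color,
    resolve_style,
)
from .sbmlio import fmt


def _shape_svg(shape, box: BoundingBox, fill: str, stroke: str, sw: float) -> str:
    x, y, w, h = box.position.x, box.position.y, box.width, box.height
    paint = (
        f' fill={quoteattr(fill)} stroke={quoteattr(stroke)}'
        f' stroke-width={quoteattr(fmt(sw))}'
    )
    if isinstance(shape, Rectangle):
        rx = shape.corner_rx / 100.0 * w
        ry = shape.corner_ry / 100.0 * h
        corner = ""
        if rx:
            corner += f' rx="{fmt(rx)}"'
        if ry:
            corner += f' ry="{fmt(ry)}"'
        return (
            f'<rect x="{fmt(x)}" y="{fmt(y)}" width="{fmt(w)}" height="{fmt(h)}"'
            f"{corner}{paint}/>"
        )
    if isinstance(shape, Ellipse):
        return (
            f'<ellipse cx="{fmt(x + w / 2)}" cy="{fmt(y + h / 2)}"'
            f' rx="{fmt(w / 2)}" ry="{fmt(h / 2)}"{paint}/>'
        )
    if isinstance(shape, Polygon):
        pts = " ".join(
            f"{fmt(x + px / 100.0 * w)},{fmt(y + py / 100.0 * h)}" for px, py in shape.points
        )
        return f'<polygon points="{pts}"{paint}/>'
    if isinstance(shape, CurvePrimitive):
        pts = " ".join(
            f"{fmt(x + px / 100.0 * w)},{fmt(y + py / 100.0 * h)}" for px, py in shape.points
        )
        return (
            f'<polyline points="{pts}" fill="none" stroke={quoteattr(stroke)}'
            f' stroke-width={quoteattr(fmt(sw))}/>'
        )
    raise LayoutError(f"cannot render shape {shape!r}")


def _curve_path(segments: list[CurveSegment]) -> str:
    parts = [f"M {fmt(segments[0].start.x)} {fmt(segments[0].start.y)}"]
    for seg in segments:
        if seg.kind == "cubic_bezier":
            parts.append(
                "C "
                f"{fmt(seg.base_point1.x)} {fmt(seg.base_point1.y)}, "
                f"{fmt(seg.base_point2.x)} {fmt(seg.base_point2.y)}, "
                f"{fmt(seg.end.x)} {fmt(seg.end.y)}"
            )
        else:
            parts.append(f"L {fmt(seg.end.x)} {fmt(seg.end.y)}")
    return " ".join(parts)


def _marker(le: LineEnding, color: str, marker_id: str) -> str:
    """SVG marker for a line ending; the local origin is the curve anchor."""
    x, y, w, h = le.bounding_box
    if isinstance(le.shape, Polygon):
        pts = " ".join(
            f"{fmt(x + px / 100.0 * w)},{fmt(y + py / 100.0 * h)}" for px, py in le.shape.points
        )
        shape_svg = f'<polygon points="{pts}" fill={quoteattr(color)}/>'
    else:
        shape_svg = (
            f'<ellipse cx="{fmt(x + w / 2)}" cy="{fmt(y + h / 2)}" rx="{fmt(w / 2)}"'
            f' ry="{fmt(h / 2)}" fill={quoteattr(color)}/>'
        )
    orient = ' orient="auto"' if le.enable_rotational_mapping else ""
    return (
        f'<marker id={quoteattr(marker_id)} viewBox="{fmt(x)} {fmt(y)} {fmt(w)} {fmt(h)}"'
        f' refX="0" refY="0" markerWidth="{fmt(w)}" markerHeight="{fmt(h)}"'
        f' markerUnits="userSpaceOnUse"{orient}>{shape_svg}</marker>'
    )


def _check_positioned(layout: Layout) -> None:
    for g in layout.all_glyphs():
        p = g.bounding_box.position
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            raise LayoutError(f"glyph {g.id!r} is not positioned")


def export_svg(layout: Layout, render: RenderInformation) -> str:
    """Render layout + styles to one deterministic SVG document."""
    _check_positioned(layout)
    out: list[str] = []
    markers: dict[str, str] = {}  # marker_id -> definition, insertion-ordered

    def marker_ref(head: str | None, color: str) -> str:
        if head in (None, "none"):
            return ""
        le = render.get_line_ending(head)
        mid = f"{head}_{color.lstrip('#')}"
        if mid not in markers:
            markers[mid] = _marker(le, color, mid)
        return mid

    def paint(group: RenderGroup) -> tuple[str, str, float]:
        fill = resolve_color(render, group.fill) or "none"
        stroke = resolve_color(render, group.stroke) or "none"
        return fill, stroke, group.stroke_width or 0.0

    body: list[str] = []

    for cg in layout.compartment_glyphs:
        group = resolve_style(render, cg)
        fill, stroke, sw = paint(group)
        for shape in group.shapes or ():
            body.append(_shape_svg(shape, cg.bounding_box, fill, stroke, sw))

    for rg in layout.reaction_glyphs:
        rgroup = resolve_style(render, rg)
        for srg in rg.species_reference_glyphs:
            if not srg.curve:
                continue
            group = resolve_style(render, srg, parent_reaction_glyph_id=rg.id)
            stroke = resolve_color(render, group.stroke) or "#000000"
            sw = group.stroke_width or 1.0
            attrs = (
                f' fill="none" stroke={quoteattr(stroke)}'
                f' stroke-width={quoteattr(fmt(sw))}'
            )
            start_m = marker_ref(group.start_head, stroke)
            end_m = marker_ref(group.end_head, stroke)
            if start_m:
                attrs += f' marker-start="url(#{start_m})"'
            if end_m:
                attrs += f' marker-end="url(#{end_m})"'
            body.append(f'<path d="{_curve_path(srg.curve)}"{attrs}/>')
        fill, stroke, sw = paint(rgroup)
        for shape in rgroup.shapes if rgroup.shapes is not None else ():
            body.append(_shape_svg(shape, rg.bounding_box, fill, stroke, sw))

    for sg in layout.species_glyphs:
        group = resolve_style(render, sg)
        fill, stroke, sw = paint(group)
        for shape in group.shapes or ():
            body.append(_shape_svg(shape, sg.bounding_box, fill, stroke, sw))

    for t in layout.text_glyphs:
        group = resolve_style(render, t)
        color = resolve_color(render, group.font_color) or "#000000"
        box = t.bounding_box
        body.append(
            f'<text x="{fmt(box.center.x)}" y="{fmt(box.center.y)}"'
            f' text-anchor="middle" dominant-baseline="central"'
            f" font-size={quoteattr(fmt(group.font_size or 12.0))}"
            f" font-family={quoteattr(group.font_family or 'sans-serif')}"
            f" fill={quoteattr(color)}>{escape(t.text)}</text>"
        )

    for g in layout.graphical_objects:
        group = resolve_style(render, g)
        fill, stroke, sw = paint(group)
        for shape in group.shapes or ():
            body.append(_shape_svg(shape, g.bounding_box, fill, stroke, sw))

    bg = resolve_color(render, render.background) or "#FFFFFF"
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1"'
        f' width="{fmt(layout.width)}" height="{fmt(layout.height)}"'
        f' viewBox="0 0 {fmt(layout.width)} {fmt(layout.height)}">'
    )
    if markers:
        out.append("<defs>" + "".join(markers.values()) + "</defs>")
    out.append(
        f'<rect x="0" y="0" width="{fmt(layout.width)}" height="{fmt(layout.height)}"'
        f" fill={quoteattr(bg)}/>"
    )
    out.extend(body)
    out.append("</svg>")
    return "\n".join(out) + "\n"
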