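"""Render-style model: color definitions, line endings (arrowheads), styles
resolved onto glyphs, style templates, and the HTML named-color table.

Styles mirror the SBML Render vocabulary: a style addresses glyphs through an
id list, a role list and/or a type list, and carries a graphical-attribute
group (stroke, fill, fonts, child shape primitives, line-ending heads).
Resolution follows a deterministic cascade — type-list styles, then role-list
styles, then id-list styles, with later-defined styles winning within a tier —
and always falls back to a complete default group, so every glyph resolves.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field, replace

from ._colortable import HTML_COLORS
from .errors import StyleError, ValidationError
from .layout import (
    CompartmentGlyph,
    GraphicalObjectGlyph,
    Layout,
    ReactionGlyph,
    SpeciesGlyph,
    SpeciesReferenceGlyph,
    TextGlyph,
)

_HEX_RE = re.compile(r"^#[0-9A-F]{6}([0-9A-F]{2})?$")

GLYPH_TYPES = (
    "COMPARTMENTGLYPH",
    "SPECIESGLYPH",
    "REACTIONGLYPH",
    "SPECIESREFERENCEGLYPH",
    "TEXTGLYPH",
    "GRAPHICALOBJECT",
)


def normalize_hex(value: str) -> str:
    """Canonical uppercase #RRGGBB[AA] form; raises StyleError otherwise."""
    v = value.strip().upper()
    if not v.startswith("#"):
        v = "#" + v
    if not _HEX_RE.match(v):
        raise StyleError(f"not a hex color: {value!r}")
    return v


def html_color(name: str) -> str:
    """Hex code of an HTML/CSS named color (case-insensitive)."""
    key = name.strip().lower()
    try:
        return HTML_COLORS[key]
    except KeyError:
        near = difflib.get_close_matches(key, HTML_COLORS, n=3)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise StyleError(f"unknown color name {name!r}{hint}") from None


# --- shape primitives ------------------------------------------------------
# Child shapes of a render group, in the glyph's local bounding-box frame.
# Polygon/curve points are fractions of the box (0..100, i.e. percent).


@dataclass
class Rectangle:
    corner_rx: float = 0.0  # corner radii, percent of box size
    corner_ry: float = 0.0


@dataclass
class Ellipse:
    pass


@dataclass
class Polygon:
    points: list[tuple[float, float]] = field(default_factory=list)  # percent coords

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError("polygon needs at least 3 vertices")


@dataclass
class CurvePrimitive:
    """An open polyline in percent coordinates (e.g. the slash of the SBGN
    empty-set symbol)."""

    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("curve primitive needs at least 2 points")


@dataclass
class ColorDefinition:
    id: str
    value: str

    def __post_init__(self):
        self.value = normalize_hex(self.value)


@dataclass
class LineEnding:
    id: str
    bounding_box: tuple[float, float, float, float]  # x, y, w, h in the local frame
    shape: Polygon | Ellipse
    enable_rotational_mapping: bool = True


#: attribute names a render group understands (SBML Render vocabulary)
GROUP_ATTRIBUTES = (
    "stroke",
    "stroke_width",
    "fill",
    "font_size",
    "font_family",
    "font_color",
    "shapes",
    "start_head",
    "end_head",
)


@dataclass
class RenderGroup:
    stroke: str | None = None
    stroke_width: float | None = None
    fill: str | None = None
    font_size: float | None = None
    font_family: str | None = None
    font_color: str | None = None
    shapes: list | None = None
    start_head: str | None = None  # line-ending id, "none", or None (unset)
    end_head: str | None = None

    def merge_over(self, base: "RenderGroup") -> "RenderGroup":
        """This group's set attributes layered over ``base``."""
        out = replace(base)
        for attr in GROUP_ATTRIBUTES:
            v = getattr(self, attr)
            if v is not None:
                setattr(out, attr, v)
        return out


@dataclass
class Style:
    id: str
    group: RenderGroup
    id_list: set[str] = field(default_factory=set)
    role_list: set[str] = field(default_factory=set)
    type_list: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not (self.id_list or self.role_list or self.type_list):
            raise ValueError("style must address at least one of id/role/type")


@dataclass
class RenderInformation:
    id: str = "netglyph_render"
    background: str = "#FFFFFF"
    color_definitions: list[ColorDefinition] = field(default_factory=list)
    line_endings: list[LineEnding] = field(default_factory=list)
    styles: list[Style] = field(default_factory=list)

    def get_line_ending(self, le_id: str) -> LineEnding:
        for le in self.line_endings:
            if le.id == le_id:
                return le
        raise KeyError(le_id)

    def validate(self) -> None:
        errors: list[tuple[str, str]] = []
        le_ids = {le.id for le in self.line_endings}
        color_ids = {c.id for c in self.color_definitions}
        for s in self.styles:
            for head in (s.group.start_head, s.group.end_head):
                if head not in (None, "none") and head not in le_ids:
                    errors.append((s.id, f"unknown line ending {head!r}"))
            for attr in ("stroke", "fill", "font_color"):
                v = getattr(s.group, attr)
                if v is None or v == "none":
                    continue
                if not v.startswith("#") and v not in color_ids:
                    errors.append((s.id, f"unresolved color {v!r} in {attr}"))
        if errors:
            raise ValidationError(errors)


# --- defaults and templates ------------------------------------------------

#: complete fallback group — resolution is total because merging starts here
DEFAULT_GROUP = RenderGroup(
    stroke="#000000",
    stroke_width=2.0,
    fill="#FFFFFF",
    font_size=12.0,
    font_family="sans-serif",
    font_color="#000000",
    shapes=[Rectangle(corner_rx=10.0, corner_ry=10.0)],
    start_head="none",
    end_head="none",
)

_ARROW_TRIANGLE = LineEnding(
    "arrow_triangle",
    (-12.0, -6.0, 12.0, 12.0),
    Polygon([(0.0, 0.0), (0.0, 100.0), (100.0, 50.0)]),
)


def apply_default_template(layout: Layout) -> RenderInformation:
    """Type-based default styles: white rounded-rectangle species, black
    2-unit reaction curves with triangular product arrowheads, light-gray
    thin-stroked compartments, black 12-point text."""
    render = RenderInformation()
    render.line_endings.append(
        LineEnding(
            _ARROW_TRIANGLE.id, _ARROW_TRIANGLE.bounding_box, _ARROW_TRIANGLE.shape
        )
    )
    render.styles.append(
        Style(
            "compartment_default",
            RenderGroup(
                stroke="#C0C0C0", stroke_width=1.0, fill="#F5F5F5",
                shapes=[Rectangle(corner_rx=5.0, corner_ry=5.0)],
            ),
            type_list={"COMPARTMENTGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "species_default",
            RenderGroup(
                stroke="#000000", stroke_width=2.0, fill="#FFFFFF",
                shapes=[Rectangle(corner_rx=10.0, corner_ry=10.0)],
            ),
            type_list={"SPECIESGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "reaction_default",
            RenderGroup(stroke="#000000", stroke_width=2.0, fill="none"),
            type_list={"REACTIONGLYPH", "SPECIESREFERENCEGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "text_default",
            RenderGroup(font_color="#000000", font_size=12.0, font_family="sans-serif"),
            type_list={"TEXTGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "product_arrow",
            RenderGroup(end_head="arrow_triangle"),
            role_list={"product", "sideproduct"},
        )
    )
    render.validate()
    return render


def _sbgn_template(layout: Layout) -> RenderInformation:
    render = apply_default_template(layout)
    render.line_endings.append(
        LineEnding(
            "production_head",
            (-14.0, -7.0, 14.0, 14.0),
            Polygon([(0.0, 0.0), (0.0, 100.0), (100.0, 50.0)]),
        )
    )
    render.line_endings.append(
        LineEnding("modulation_head", (-12.0, -6.0, 12.0, 12.0), Ellipse())
    )
    render.styles.append(
        Style(
            "sbgn_species",
            RenderGroup(
                stroke="#000000", stroke_width=2.0, fill="#FFFFFF",
                shapes=[Rectangle(corner_rx=25.0, corner_ry=25.0)],
            ),
            type_list={"SPECIESGLYPH"},
        )
    )
    # small square process node at the reaction center
    render.styles.append(
        Style(
            "sbgn_process",
            RenderGroup(stroke="#000000", stroke_width=2.0, fill="#FFFFFF",
                        shapes=[Rectangle()]),
            type_list={"REACTIONGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "sbgn_consumption",
            RenderGroup(stroke="#000000", stroke_width=2.0, end_head="none"),
            role_list={"substrate", "sidesubstrate"},
        )
    )
    render.styles.append(
        Style(
            "sbgn_production",
            RenderGroup(stroke="#000000", stroke_width=2.0, end_head="production_head"),
            role_list={"product", "sideproduct"},
        )
    )
    render.styles.append(
        Style(
            "sbgn_modulation",
            RenderGroup(stroke="#000000", stroke_width=2.0, end_head="modulation_head"),
            role_list={"modifier"},
        )
    )
    # empty-set symbol for source/sink glyphs: circle plus diagonal slash
    empty_ids = {g.id for g in layout.species_glyphs if g.species_id is None}
    if empty_ids:
        render.styles.append(
            Style(
                "sbgn_empty_set",
                RenderGroup(
                    stroke="#000000", stroke_width=2.0, fill="#FFFFFF",
                    shapes=[Ellipse(), CurvePrimitive([(85.0, 15.0), (15.0, 85.0)])],
                ),
                id_list=empty_ids,
            )
        )
    render.validate()
    return render


def _escher_template(layout: Layout) -> RenderInformation:
    render = apply_default_template(layout)
    render.line_endings.append(
        LineEnding(
            "escher_head",
            (-20.0, -8.0, 20.0, 16.0),
            Polygon([(0.0, 0.0), (0.0, 100.0), (100.0, 50.0)]),
        )
    )
    render.styles.append(
        Style(
            "escher_species",
            RenderGroup(
                stroke="#6A4A8C", stroke_width=2.0, fill="#B595CB", shapes=[Ellipse()]
            ),
            type_list={"SPECIESGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "escher_reaction",
            RenderGroup(stroke="#334E75", stroke_width=18.0, fill="none",
                        end_head="escher_head"),
            type_list={"REACTIONGLYPH", "SPECIESREFERENCEGLYPH"},
        )
    )
    render.styles.append(
        Style(
            "escher_text",
            RenderGroup(font_color="#1A1A1A", font_size=20.0,
                        font_family="sans-serif-bold"),
            type_list={"TEXTGLYPH"},
        )
    )
    render.validate()
    return render


TEMPLATES = {
    "default": apply_default_template,
    "sbgn": _sbgn_template,
    "escher": _escher_template,
}


def apply_template(layout: Layout, name: str) -> RenderInformation:
    """Build render information from a named template (default/sbgn/escher)."""
    try:
        builder = TEMPLATES[name]
    except KeyError:
        raise StyleError(
            f"unknown template {name!r}; available: {', '.join(sorted(TEMPLATES))}"
        ) from None
    return builder(layout)


# --- batch mutation --------------------------------------------------------

_COLOR_ATTRS = ("stroke", "fill", "font_color")


def _intern_color(render: RenderInformation, hexval: str) -> None:
    cid = "c_" + hexval.lstrip("#")
    if not any(c.id == cid for c in render.color_definitions):
        render.color_definitions.append(ColorDefinition(cid, hexval))


def set_group_attribute(
    render: RenderInformation, glyph_ids: set[str], attribute: str, value
) -> RenderInformation:
    """Set one render attribute on exactly the given glyphs via an id-list
    style (created, or updated when a style for that exact id set exists).

    Hex color values are normalized and interned as color definitions.  An
    empty glyph set is a no-op.
    """
    if attribute not in GROUP_ATTRIBUTES:
        raise StyleError(
            f"unknown attribute {attribute!r}; expected one of {GROUP_ATTRIBUTES}"
        )
    glyph_ids = set(glyph_ids)
    if not glyph_ids:
        return render
    if attribute in _COLOR_ATTRS and isinstance(value, str) and value != "none":
        value = normalize_hex(value)
        _intern_color(render, value)
    for s in render.styles:
        if s.id_list == glyph_ids and not s.role_list and not s.type_list:
            setattr(s.group, attribute, value)
            break
    else:
        n = sum(1 for s in render.styles if s.id_list)
        group = RenderGroup(**{attribute: value})
        render.styles.append(Style(f"idstyle_{n + 1}", group, id_list=glyph_ids))
    render.validate()
    return render


# --- resolution ------------------------------------------------------------


def glyph_type(glyph) -> str:
    if isinstance(glyph, SpeciesGlyph):
        return "SPECIESGLYPH"
    if isinstance(glyph, ReactionGlyph):
        return "REACTIONGLYPH"
    if isinstance(glyph, SpeciesReferenceGlyph):
        return "SPECIESREFERENCEGLYPH"
    if isinstance(glyph, TextGlyph):
        return "TEXTGLYPH"
    if isinstance(glyph, CompartmentGlyph):
        return "COMPARTMENTGLYPH"
    if isinstance(glyph, GraphicalObjectGlyph):
        return "GRAPHICALOBJECT"
    raise StyleError(f"unknown glyph kind {type(glyph).__name__}")


def resolve_style(
    render: RenderInformation, glyph, *, parent_reaction_glyph_id: str | None = None
) -> RenderGroup:
    """Fully resolved render group for a glyph (pure function, always total).

    Cascade: type-list styles, then role-list styles, then id-list styles;
    later-defined styles win within a tier; anything left unset falls back to
    the package defaults.  A species-reference glyph additionally matches
    styles addressed at its parent reaction glyph's id, so batch edits on
    reactions restyle their curves.
    """
    gtype = glyph_type(glyph)
    role = glyph.role if isinstance(glyph, SpeciesReferenceGlyph) else None
    ids = {glyph.id}
    if parent_reaction_glyph_id is not None:
        ids.add(parent_reaction_glyph_id)

    out = replace(DEFAULT_GROUP)
    for tier in ("type", "role", "id"):
        for s in render.styles:
            match = (
                (tier == "type" and gtype in s.type_list)
                or (tier == "role" and role is not None and role in s.role_list)
                or (tier == "id" and ids & s.id_list)
            )
            if match:
                out = s.group.merge_over(out)
    return out


def resolve_color(render: RenderInformation, value: str | None) -> str | None:
    """Map a color-definition id to its hex value; hex values pass through."""
    if value is None or value == "none" or value.startswith("#"):
        return value
    for c in render.color_definitions:
        if c.id == value:
            return c.value
    return value
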