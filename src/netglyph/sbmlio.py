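"""SBML Level 3 reading and writing with the Layout and Render packages.

The writer emits a single canonicalized L3V1 document — fixed element order,
6-decimal fixed-point numbers with trailing zeros trimmed — so identical
in-memory state always yields byte-identical text (the basis for golden-file
testing).  The reader inverts the writer exactly and degrades gracefully on
foreign documents: a model without layout/render comes back with those parts
flagged absent so the caller can auto-generate them.

Two details use a small extension namespace (``ng``) because the Render
vocabulary has no standard slot for them: a font color distinct from the
shape stroke, and the marker distinguishing "explicitly no shapes" (curve-only
reaction display) from "shapes unset".  Consumers that ignore unknown
attributes see plain Layout/Render data.
"""

from __future__ import annotations

import warnings

from lxml import etree

from .errors import SBMLReadError, ValidationError
from .layout import (
    BoundingBox,
    CompartmentGlyph,
    CurveSegment,
    GraphicalObjectGlyph,
    Layout,
    Point,
    ReactionGlyph,
    SpeciesGlyph,
    SpeciesReferenceGlyph,
    TextGlyph,
)
from .model import Network, Participant, Reaction, Species
from .style import (
    ColorDefinition,
    CurvePrimitive,
    Ellipse,
    LineEnding,
    Polygon,
    Rectangle,
    RenderGroup,
    RenderInformation,
    Style,
)

CORE_NS = "http://www.sbml.org/sbml/level3/version1/core"
LAYOUT_NS = "http://www.sbml.org/sbml/level3/version1/layout/version1"
RENDER_NS = "http://www.sbml.org/sbml/level3/version1/render/version1"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
NG_NS = "http://netglyph.dev/extension/version1"

NSMAP = {None: CORE_NS, "layout": LAYOUT_NS, "render": RENDER_NS, "xsi": XSI_NS, "ng": NG_NS}


def fmt(v: float) -> str:
    """Canonical 6-decimal fixed-point number, trailing zeros trimmed."""
    s = f"{float(v):.6f}".rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def L(tag: str) -> str:
    return _q(LAYOUT_NS, tag)


def R(tag: str) -> str:
    return _q(RENDER_NS, tag)


# --- writing ---------------------------------------------------------------


def _write_bbox(parent, box: BoundingBox) -> None:
    bb = etree.SubElement(parent, L("boundingBox"))
    etree.SubElement(
        bb, L("position"), {L("x"): fmt(box.position.x), L("y"): fmt(box.position.y)}
    )
    etree.SubElement(
        bb, L("dimensions"), {L("width"): fmt(box.width), L("height"): fmt(box.height)}
    )


def _write_curve(parent, segments: list[CurveSegment]) -> None:
    curve = etree.SubElement(parent, L("curve"))
    los = etree.SubElement(curve, L("listOfCurveSegments"))
    for seg in segments:
        kind = "CubicBezier" if seg.kind == "cubic_bezier" else "LineSegment"
        el = etree.SubElement(los, L("curveSegment"), {_q(XSI_NS, "type"): kind})
        etree.SubElement(el, L("start"), {L("x"): fmt(seg.start.x), L("y"): fmt(seg.start.y)})
        etree.SubElement(el, L("end"), {L("x"): fmt(seg.end.x), L("y"): fmt(seg.end.y)})
        if seg.kind == "cubic_bezier":
            etree.SubElement(
                el,
                L("basePoint1"),
                {L("x"): fmt(seg.base_point1.x), L("y"): fmt(seg.base_point1.y)},
            )
            etree.SubElement(
                el,
                L("basePoint2"),
                {L("x"): fmt(seg.base_point2.x), L("y"): fmt(seg.base_point2.y)},
            )


def _pct(v: float) -> str:
    return fmt(v) + "%"


def _write_shape(g_el, shape) -> None:
    if isinstance(shape, Rectangle):
        attrs = {
            R("x"): "0", R("y"): "0", R("width"): "100%", R("height"): "100%",
        }
        if shape.corner_rx:
            attrs[R("rx")] = _pct(shape.corner_rx)
        if shape.corner_ry:
            attrs[R("ry")] = _pct(shape.corner_ry)
        etree.SubElement(g_el, R("rectangle"), attrs)
    elif isinstance(shape, Ellipse):
        etree.SubElement(
            g_el,
            R("ellipse"),
            {R("cx"): "50%", R("cy"): "50%", R("rx"): "50%", R("ry"): "50%"},
        )
    elif isinstance(shape, (Polygon, CurvePrimitive)):
        tag = "polygon" if isinstance(shape, Polygon) else "curve"
        poly = etree.SubElement(g_el, R(tag))
        los = etree.SubElement(poly, R("listOfElements"))
        for x, y in shape.points:
            etree.SubElement(
                los,
                R("element"),
                {_q(XSI_NS, "type"): "RenderPoint", R("x"): _pct(x), R("y"): _pct(y)},
            )
    else:  # pragma: no cover - guarded by dataclass types
        raise ValidationError([("", f"unknown shape primitive {shape!r}")])


def _write_group(parent, group: RenderGroup) -> None:
    attrs: dict[str, str] = {}
    if group.stroke is not None:
        attrs[R("stroke")] = group.stroke
    if group.stroke_width is not None:
        attrs[R("stroke-width")] = fmt(group.stroke_width)
    if group.fill is not None:
        attrs[R("fill")] = group.fill
    if group.font_size is not None:
        attrs[R("font-size")] = fmt(group.font_size)
    if group.font_family is not None:
        attrs[R("font-family")] = group.font_family
    if group.font_color is not None:
        attrs[_q(NG_NS, "fontColor")] = group.font_color
    if group.start_head is not None:
        attrs[R("startHead")] = group.start_head
    if group.end_head is not None:
        attrs[R("endHead")] = group.end_head
    if group.shapes is not None and len(group.shapes) == 0:
        attrs[_q(NG_NS, "emptyShapes")] = "true"
    g_el = etree.SubElement(parent, R("g"), attrs)
    for shape in group.shapes or ():
        _write_shape(g_el, shape)


def write_sbml(network: Network, layout: Layout, render: RenderInformation) -> str:
    """Serialize model + layout + local render information to canonical SBML."""
    network.validate()
    layout.validate()
    render.validate()

    root = etree.Element(
        _q(CORE_NS, "sbml"),
        {
            "level": "3",
            "version": "1",
            _q(LAYOUT_NS, "required"): "false",
            _q(RENDER_NS, "required"): "false",
        },
        nsmap=NSMAP,
    )
    model = etree.SubElement(root, _q(CORE_NS, "model"), {"id": "netglyph_model"})

    loc = etree.SubElement(model, _q(CORE_NS, "listOfCompartments"))
    for cid, cname in network.compartments:
        etree.SubElement(
            loc,
            _q(CORE_NS, "compartment"),
            {"id": cid, "name": cname, "constant": "true"},
        )
    if network.species:
        los = etree.SubElement(model, _q(CORE_NS, "listOfSpecies"))
        for s in network.species:
            etree.SubElement(
                los,
                _q(CORE_NS, "species"),
                {
                    "id": s.id,
                    "name": s.name,
                    "compartment": s.compartment_id,
                    "hasOnlySubstanceUnits": "false",
                    "boundaryCondition": "false",
                    "constant": "false",
                },
            )
    if network.reactions:
        lor = etree.SubElement(model, _q(CORE_NS, "listOfReactions"))
        for r in network.reactions:
            rel = etree.SubElement(
                lor,
                _q(CORE_NS, "reaction"),
                {"id": r.id, "reversible": "false", "fast": "false"},
            )
            for tag, role in (
                ("listOfReactants", "reactant"),
                ("listOfProducts", "product"),
            ):
                parts = r.by_role(role)
                if parts:
                    lst = etree.SubElement(rel, _q(CORE_NS, tag))
                    for p in parts:
                        etree.SubElement(
                            lst,
                            _q(CORE_NS, "speciesReference"),
                            {
                                "species": p.species_id,
                                "stoichiometry": fmt(p.stoichiometry),
                                "constant": "true",
                            },
                        )
            mods = r.modifiers
            if mods:
                lst = etree.SubElement(rel, _q(CORE_NS, "listOfModifiers"))
                for p in mods:
                    etree.SubElement(
                        lst,
                        _q(CORE_NS, "modifierSpeciesReference"),
                        {"species": p.species_id},
                    )

    lol = etree.SubElement(model, L("listOfLayouts"))
    lay = etree.SubElement(lol, L("layout"), {L("id"): layout.id})
    etree.SubElement(
        lay, L("dimensions"), {L("width"): fmt(layout.width), L("height"): fmt(layout.height)}
    )
    if layout.compartment_glyphs:
        lst = etree.SubElement(lay, L("listOfCompartmentGlyphs"))
        for cg in layout.compartment_glyphs:
            el = etree.SubElement(
                lst, L("compartmentGlyph"), {L("id"): cg.id, L("compartment"): cg.compartment_id}
            )
            _write_bbox(el, cg.bounding_box)
    if layout.species_glyphs:
        lst = etree.SubElement(lay, L("listOfSpeciesGlyphs"))
        for sg in layout.species_glyphs:
            attrs = {L("id"): sg.id}
            if sg.species_id is not None:
                attrs[L("species")] = sg.species_id
            el = etree.SubElement(lst, L("speciesGlyph"), attrs)
            _write_bbox(el, sg.bounding_box)
    if layout.reaction_glyphs:
        lst = etree.SubElement(lay, L("listOfReactionGlyphs"))
        for rg in layout.reaction_glyphs:
            el = etree.SubElement(
                lst, L("reactionGlyph"), {L("id"): rg.id, L("reaction"): rg.reaction_id}
            )
            _write_bbox(el, rg.bounding_box)
            if rg.species_reference_glyphs:
                srgl = etree.SubElement(el, L("listOfSpeciesReferenceGlyphs"))
                for srg in rg.species_reference_glyphs:
                    sel = etree.SubElement(
                        srgl,
                        L("speciesReferenceGlyph"),
                        {
                            L("id"): srg.id,
                            L("speciesGlyph"): srg.species_glyph_id,
                            L("role"): srg.role,
                        },
                    )
                    if srg.curve:
                        _write_curve(sel, srg.curve)
    if layout.text_glyphs:
        lst = etree.SubElement(lay, L("listOfTextGlyphs"))
        for t in layout.text_glyphs:
            el = etree.SubElement(
                lst,
                L("textGlyph"),
                {L("id"): t.id, L("graphicalObject"): t.target_glyph_id, L("text"): t.text},
            )
            _write_bbox(el, t.bounding_box)
    if layout.graphical_objects:
        lst = etree.SubElement(lay, L("listOfAdditionalGraphicalObjects"))
        for g in layout.graphical_objects:
            el = etree.SubElement(lst, L("graphicalObject"), {L("id"): g.id})
            _write_bbox(el, g.bounding_box)

    lori = etree.SubElement(lay, R("listOfRenderInformation"))
    ri = etree.SubElement(
        lori,
        R("renderInformation"),
        {R("id"): render.id, R("backgroundColor"): render.background},
    )
    if render.color_definitions:
        lst = etree.SubElement(ri, R("listOfColorDefinitions"))
        for c in render.color_definitions:
            etree.SubElement(
                lst, R("colorDefinition"), {R("id"): c.id, R("value"): c.value}
            )
    if render.line_endings:
        lst = etree.SubElement(ri, R("listOfLineEndings"))
        for le in render.line_endings:
            el = etree.SubElement(
                lst,
                R("lineEnding"),
                {
                    R("id"): le.id,
                    R("enableRotationalMapping"): "true" if le.enable_rotational_mapping else "false",
                },
            )
            x, y, w, h = le.bounding_box
            _write_bbox(el, BoundingBox(Point(x, y), w, h))
            g_el = etree.SubElement(el, R("g"))
            _write_shape(g_el, le.shape)
    if render.styles:
        lst = etree.SubElement(ri, R("listOfStyles"))
        for s in render.styles:
            attrs = {R("id"): s.id}
            if s.type_list:
                attrs[R("typeList")] = " ".join(sorted(s.type_list))
            if s.role_list:
                attrs[R("roleList")] = " ".join(sorted(s.role_list))
            if s.id_list:
                attrs[R("idList")] = " ".join(sorted(s.id_list))
            el = etree.SubElement(lst, R("style"), attrs)
            _write_group(el, s.group)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


# --- reading ---------------------------------------------------------------


def _read_point(el) -> Point:
    return Point(float(el.get(L("x"))), float(el.get(L("y"))))


def _read_bbox(parent) -> BoundingBox:
    bb = parent.find(L("boundingBox"))
    if bb is None:
        return BoundingBox(Point(0, 0), 0, 0)
    pos = bb.find(L("position"))
    dim = bb.find(L("dimensions"))
    return BoundingBox(
        _read_point(pos), float(dim.get(L("width"))), float(dim.get(L("height")))
    )


def _read_curve(parent) -> list[CurveSegment]:
    curve = parent.find(L("curve"))
    if curve is None:
        return []
    out = []
    for seg in curve.findall(L("listOfCurveSegments") + "/" + L("curveSegment")):
        kind = seg.get(_q(XSI_NS, "type"), "LineSegment")
        start = _read_point(seg.find(L("start")))
        end = _read_point(seg.find(L("end")))
        if kind == "CubicBezier":
            out.append(
                CurveSegment(
                    "cubic_bezier",
                    start,
                    end,
                    _read_point(seg.find(L("basePoint1"))),
                    _read_point(seg.find(L("basePoint2"))),
                )
            )
        else:
            out.append(CurveSegment("line", start, end))
    return out


def _strip_pct(v: str) -> float:
    return float(v.rstrip("%"))


def _read_shape(el):
    tag = etree.QName(el).localname
    if tag == "rectangle":
        return Rectangle(
            corner_rx=_strip_pct(el.get(R("rx"), "0")),
            corner_ry=_strip_pct(el.get(R("ry"), "0")),
        )
    if tag == "ellipse":
        return Ellipse()
    if tag in ("polygon", "curve"):
        pts = [
            (_strip_pct(p.get(R("x"))), _strip_pct(p.get(R("y"))))
            for p in el.findall(R("listOfElements") + "/" + R("element"))
        ]
        return Polygon(pts) if tag == "polygon" else CurvePrimitive(pts)
    return None


def _read_group(parent) -> RenderGroup:
    g_el = parent.find(R("g"))
    group = RenderGroup()
    if g_el is None:
        return group
    group.stroke = g_el.get(R("stroke"))
    sw = g_el.get(R("stroke-width"))
    group.stroke_width = float(sw) if sw is not None else None
    group.fill = g_el.get(R("fill"))
    fs = g_el.get(R("font-size"))
    group.font_size = float(fs) if fs is not None else None
    group.font_family = g_el.get(R("font-family"))
    group.font_color = g_el.get(_q(NG_NS, "fontColor"))
    group.start_head = g_el.get(R("startHead"))
    group.end_head = g_el.get(R("endHead"))
    shapes = [s for s in (_read_shape(c) for c in g_el) if s is not None]
    if shapes:
        group.shapes = shapes
    elif g_el.get(_q(NG_NS, "emptyShapes")) == "true":
        group.shapes = []
    return group


def read_sbml(text: str | bytes) -> tuple[Network, Layout | None, RenderInformation | None]:
    """Parse an SBML document; layout/render come back as None when absent."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise SBMLReadError(f"not well-formed XML: {exc}") from None
    if etree.QName(root).localname != "sbml":
        raise SBMLReadError("root element is not <sbml>")
    ns = etree.QName(root).namespace
    if ns != CORE_NS:
        warnings.warn(f"unexpected SBML namespace {ns!r}; attempting best-effort parse")
    core = ns or CORE_NS

    def C(tag):
        return _q(core, tag)

    model = root.find(C("model"))
    if model is None:
        raise SBMLReadError("document has no <model>")

    compartments = [
        (c.get("id"), c.get("name", c.get("id")))
        for c in model.findall(C("listOfCompartments") + "/" + C("compartment"))
    ]
    species = [
        Species(s.get("id"), s.get("name", s.get("id")), s.get("compartment"))
        for s in model.findall(C("listOfSpecies") + "/" + C("species"))
    ]
    reactions = []
    for rel in model.findall(C("listOfReactions") + "/" + C("reaction")):
        parts: list[Participant] = []
        for tag, role in (("listOfReactants", "reactant"), ("listOfProducts", "product")):
            for sr in rel.findall(C(tag) + "/" + C("speciesReference")):
                parts.append(
                    Participant(sr.get("species"), role, float(sr.get("stoichiometry", "1")))
                )
        for sr in rel.findall(C("listOfModifiers") + "/" + C("modifierSpeciesReference")):
            parts.append(Participant(sr.get("species"), "modifier"))
        reactions.append(Reaction(rel.get("id"), parts))
    if not compartments:
        compartments = [("default_compartment", "default_compartment")]
        for s in species:
            s.compartment_id = "default_compartment"
    network = Network(species, reactions, compartments)
    network.validate()

    lay_el = model.find(L("listOfLayouts") + "/" + L("layout"))
    if lay_el is None:
        return network, None, None

    dim = lay_el.find(L("dimensions"))
    layout = Layout(
        id=lay_el.get(L("id"), "layout"),
        width=float(dim.get(L("width"))) if dim is not None else 0.0,
        height=float(dim.get(L("height"))) if dim is not None else 0.0,
    )
    for el in lay_el.findall(L("listOfCompartmentGlyphs") + "/" + L("compartmentGlyph")):
        layout.compartment_glyphs.append(
            CompartmentGlyph(el.get(L("id")), el.get(L("compartment")), _read_bbox(el))
        )
    seen_species: set[str] = set()
    for el in lay_el.findall(L("listOfSpeciesGlyphs") + "/" + L("speciesGlyph")):
        sid = el.get(L("species"))
        is_alias = sid is not None and sid in seen_species
        if sid is not None:
            seen_species.add(sid)
        layout.species_glyphs.append(
            SpeciesGlyph(el.get(L("id")), sid, _read_bbox(el), is_alias=is_alias)
        )
    for el in lay_el.findall(L("listOfReactionGlyphs") + "/" + L("reactionGlyph")):
        rg = ReactionGlyph(el.get(L("id")), el.get(L("reaction")), _read_bbox(el))
        for sel in el.findall(
            L("listOfSpeciesReferenceGlyphs") + "/" + L("speciesReferenceGlyph")
        ):
            rg.species_reference_glyphs.append(
                SpeciesReferenceGlyph(
                    sel.get(L("id")),
                    sel.get(L("speciesGlyph")),
                    sel.get(L("role"), "substrate"),
                    _read_curve(sel),
                )
            )
        layout.reaction_glyphs.append(rg)
    for el in lay_el.findall(L("listOfTextGlyphs") + "/" + L("textGlyph")):
        layout.text_glyphs.append(
            TextGlyph(
                el.get(L("id")),
                el.get(L("graphicalObject"), el.get(L("originOfText"))),
                el.get(L("text"), ""),
                _read_bbox(el),
            )
        )
    for el in lay_el.findall(
        L("listOfAdditionalGraphicalObjects") + "/" + L("graphicalObject")
    ):
        layout.graphical_objects.append(
            GraphicalObjectGlyph(el.get(L("id")), _read_bbox(el))
        )
    layout.validate()

    ri = lay_el.find(R("listOfRenderInformation") + "/" + R("renderInformation"))
    if ri is None:
        return network, layout, None
    render = RenderInformation(
        id=ri.get(R("id"), "render"), background=ri.get(R("backgroundColor"), "#FFFFFF")
    )
    for el in ri.findall(R("listOfColorDefinitions") + "/" + R("colorDefinition")):
        render.color_definitions.append(ColorDefinition(el.get(R("id")), el.get(R("value"))))
    for el in ri.findall(R("listOfLineEndings") + "/" + R("lineEnding")):
        box = _read_bbox(el)
        g_el = el.find(R("g"))
        shape = None
        if g_el is not None:
            for c in g_el:
                shape = _read_shape(c)
                if shape is not None:
                    break
        render.line_endings.append(
            LineEnding(
                el.get(R("id")),
                (box.position.x, box.position.y, box.width, box.height),
                shape if shape is not None else Ellipse(),
                el.get(R("enableRotationalMapping"), "true") == "true",
            )
        )
    for el in ri.findall(R("listOfStyles") + "/" + R("style")):
        def _set(attr):
            v = el.get(R(attr))
            return set(v.split()) if v else set()

        render.styles.append(
            Style(
                el.get(R("id")),
                _read_group(el),
                id_list=_set("idList"),
                role_list=_set("roleList"),
                type_list=_set("typeList"),
            )
        )
    render.validate()
    return network, layout, render


# --- structural document validation ---------------------------------------


def validate_document(text: str | bytes) -> list[tuple[str, str]]:
    """Structural validation of a written document: well-formed XML, required
    SBML attributes, resolvable cross-references, declared package
    namespaces.  Returns the (element_id, message) error list (empty = valid).
    """
    errors: list[tuple[str, str]] = []
    try:
        network, layout, render = read_sbml(text)
    except (SBMLReadError, ValidationError) as exc:
        return [("document", str(exc))]
    root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    if root.get("level") != "3":
        errors.append(("sbml", "level attribute must be 3"))
    declared = set(root.nsmap.values())
    if layout is not None and LAYOUT_NS not in declared:
        errors.append(("sbml", "layout namespace not declared"))
    if render is not None and RENDER_NS not in declared:
        errors.append(("sbml", "render namespace not declared"))
    for sr in root.iter(_q(CORE_NS, "speciesReference")):
        if sr.get("species") is None:
            errors.append(("speciesReference", "missing species attribute"))
        if sr.get("constant") is None:
            errors.append(("speciesReference", "missing required 'constant'"))
    for sp in root.iter(_q(CORE_NS, "species")):
        for attr in ("compartment", "hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if sp.get(attr) is None:
                errors.append((sp.get("id", "species"), f"missing required {attr!r}"))
    return errors
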