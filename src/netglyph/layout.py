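"""Geometric document model: glyphs, bounding boxes, curves, and automatic
glyph generation for every model element.

Coordinates are real-valued canvas units in the SBML Layout frame: top-left
origin, y increasing downward.  Every model element receives a glyph; species
may additionally receive alias glyphs (extra visual copies, typically for
ubiquitous cofactors) and reactions may receive source/sink pseudo-glyphs that
have no model counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import LayoutError, ValidationError
from .model import Network

SRG_ROLES = ("substrate", "product", "modifier", "sidesubstrate", "sideproduct")

#: participant role -> species-reference-glyph role
ROLE_MAP = {"reactant": "substrate", "product": "product", "modifier": "modifier"}

# default glyph geometry (canvas units)
SPECIES_W, SPECIES_H = 60.0, 36.0
REACTION_W, REACTION_H = 20.0, 20.0
SOURCE_SINK_W, SOURCE_SINK_H = 36.0, 36.0
COMPARTMENT_MARGIN_FRAC = 0.05


@dataclass
class Point:
    x: float
    y: float

    def __add__(self, other: "Point") -> "Point":
        return Point(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "Point") -> "Point":
        return Point(self.x - other.x, self.y - other.y)

    def scaled(self, f: float) -> "Point":
        return Point(self.x * f, self.y * f)

    def norm(self) -> float:
        return math.hypot(self.x, self.y)

    def distance(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass
class BoundingBox:
    position: Point  # top-left corner
    width: float
    height: float

    def __post_init__(self):
        if self.width < 0 or self.height < 0:
            raise ValueError("bounding box dimensions must be >= 0")

    @property
    def center(self) -> Point:
        return Point(self.position.x + self.width / 2, self.position.y + self.height / 2)

    def move_center_to(self, c: Point) -> None:
        self.position = Point(c.x - self.width / 2, c.y - self.height / 2)

    def contains(self, p: Point) -> bool:
        return (
            self.position.x <= p.x <= self.position.x + self.width
            and self.position.y <= p.y <= self.position.y + self.height
        )

    def contains_box(self, other: "BoundingBox") -> bool:
        return self.contains(other.position) and self.contains(
            Point(other.position.x + other.width, other.position.y + other.height)
        )


@dataclass
class CurveSegment:
    kind: str  # "line" | "cubic_bezier"
    start: Point
    end: Point
    base_point1: Point | None = None
    base_point2: Point | None = None

    def __post_init__(self):
        if self.kind == "line":
            if self.base_point1 is not None or self.base_point2 is not None:
                raise ValueError("line segments carry no base points")
        elif self.kind == "cubic_bezier":
            if self.base_point1 is None or self.base_point2 is None:
                raise ValueError("cubic segments need both base points")
        else:
            raise ValueError(f"unknown segment kind {self.kind!r}")


def line(start: Point, end: Point) -> CurveSegment:
    return CurveSegment("line", start, end)


def cubic(start: Point, end: Point, bp1: Point, bp2: Point) -> CurveSegment:
    return CurveSegment("cubic_bezier", start, end, bp1, bp2)


@dataclass
class SpeciesGlyph:
    id: str
    species_id: str | None  # None = source/sink pseudo-glyph
    bounding_box: BoundingBox
    is_alias: bool = False

    def __post_init__(self):
        if self.is_alias and self.species_id is None:
            raise ValueError("alias glyph must reference a species")


@dataclass
class SpeciesReferenceGlyph:
    id: str
    species_glyph_id: str
    role: str
    curve: list[CurveSegment] = field(default_factory=list)

    def __post_init__(self):
        if self.role not in SRG_ROLES:
            raise ValueError(f"role must be one of {SRG_ROLES}, got {self.role!r}")


@dataclass
class ReactionGlyph:
    id: str
    reaction_id: str
    bounding_box: BoundingBox
    species_reference_glyphs: list[SpeciesReferenceGlyph] = field(default_factory=list)

    @property
    def center(self) -> Point:
        return self.bounding_box.center


@dataclass
class TextGlyph:
    id: str
    target_glyph_id: str
    text: str
    bounding_box: BoundingBox


@dataclass
class CompartmentGlyph:
    id: str
    compartment_id: str
    bounding_box: BoundingBox


@dataclass
class GraphicalObjectGlyph:
    """A layout element with no model counterpart (color-bar segments etc.)."""

    id: str
    bounding_box: BoundingBox


@dataclass
class Layout:
    id: str = "netglyph_layout"
    width: float = 1000.0
    height: float = 1000.0
    compartment_glyphs: list[CompartmentGlyph] = field(default_factory=list)
    species_glyphs: list[SpeciesGlyph] = field(default_factory=list)
    reaction_glyphs: list[ReactionGlyph] = field(default_factory=list)
    text_glyphs: list[TextGlyph] = field(default_factory=list)
    graphical_objects: list[GraphicalObjectGlyph] = field(default_factory=list)
    #: ids of species-reference glyphs whose curve was custom-shaped by an
    #: arrangement operator (protected from standard re-routing); session
    #: bookkeeping only, not part of document state
    custom_curves: set[str] = field(default_factory=set, compare=False, repr=False)

    # -- lookups ------------------------------------------------------------

    def all_glyphs(self):
        yield from self.compartment_glyphs
        yield from self.species_glyphs
        yield from self.reaction_glyphs
        yield from self.graphical_objects
        yield from self.text_glyphs

    def glyph_ids(self) -> set[str]:
        return {g.id for g in self.all_glyphs()}

    def get_glyph(self, glyph_id: str):
        for g in self.all_glyphs():
            if g.id == glyph_id:
                return g
        raise KeyError(glyph_id)

    def get_species_glyph(self, glyph_id: str) -> SpeciesGlyph:
        for g in self.species_glyphs:
            if g.id == glyph_id:
                return g
        raise KeyError(glyph_id)

    def species_glyphs_of(self, species_id: str) -> list[SpeciesGlyph]:
        return [g for g in self.species_glyphs if g.species_id == species_id]

    def get_reaction_glyph(self, reaction_id: str) -> ReactionGlyph:
        for g in self.reaction_glyphs:
            if g.reaction_id == reaction_id:
                return g
        raise LayoutError(f"no reaction glyph for reaction {reaction_id!r}")

    def text_glyphs_of(self, target_glyph_id: str) -> list[TextGlyph]:
        return [t for t in self.text_glyphs if t.target_glyph_id == target_glyph_id]

    def glyph_degree(self, glyph_id: str) -> int:
        """Number of species-reference glyphs (across all reactions) hitting a glyph."""
        return sum(
            1
            for rg in self.reaction_glyphs
            for srg in rg.species_reference_glyphs
            if srg.species_glyph_id == glyph_id
        )

    # -- mutation helpers ---------------------------------------------------

    def move_glyph_center(self, glyph_id: str, center: Point) -> None:
        """Move a glyph so its box center lands on ``center``; attached text
        glyphs travel with it."""
        g = self.get_glyph(glyph_id)
        old = g.bounding_box.center
        g.bounding_box.move_center_to(center)
        dx, dy = center.x - old.x, center.y - old.y
        for t in self.text_glyphs_of(glyph_id):
            t.bounding_box.position = Point(
                t.bounding_box.position.x + dx, t.bounding_box.position.y + dy
            )

    def validate(self) -> None:
        errors: list[tuple[str, str]] = []
        ids: set[str] = set()
        for g in self.all_glyphs():
            if g.id in ids:
                errors.append((g.id, "duplicate glyph id"))
            ids.add(g.id)
        sg_ids = {g.id for g in self.species_glyphs}
        for t in self.text_glyphs:
            if t.target_glyph_id not in ids:
                errors.append((t.id, f"text target {t.target_glyph_id!r} missing"))
        for rg in self.reaction_glyphs:
            for srg in rg.species_reference_glyphs:
                if srg.species_glyph_id not in sg_ids:
                    errors.append(
                        (srg.id, f"species glyph {srg.species_glyph_id!r} missing")
                    )
        if errors:
            raise ValidationError(errors)


# --- automatic glyph generation -------------------------------------------


def generate_layout(network: Network, canvas: tuple[float, float]) -> Layout:
    """Create one glyph per model element with placeholder (origin) positions.

    Produces a species glyph + text glyph per species, a reaction glyph with
    one species-reference glyph per participant, a compartment glyph + text
    glyph per compartment.  Sizes are the module defaults; positions are left
    at the origin until the auto-layout or an arrangement operator runs.
    """
    try:
        network.validate()
    except ValidationError:
        raise
    w, h = float(canvas[0]), float(canvas[1])
    if w <= 0 or h <= 0:
        raise LayoutError("canvas dimensions must be positive")
    layout = Layout(width=w, height=h)

    m = COMPARTMENT_MARGIN_FRAC
    for cid, cname in network.compartments:
        cg = CompartmentGlyph(
            f"{cid}_glyph", cid, BoundingBox(Point(w * m, h * m), w * (1 - 2 * m), h * (1 - 2 * m))
        )
        layout.compartment_glyphs.append(cg)
        layout.text_glyphs.append(
            TextGlyph(f"{cg.id}_text", cg.id, cname or cid, replace_box(cg.bounding_box))
        )

    for s in network.species:
        sg = SpeciesGlyph(f"{s.id}_glyph", s.id, BoundingBox(Point(0, 0), SPECIES_W, SPECIES_H))
        layout.species_glyphs.append(sg)
        layout.text_glyphs.append(
            TextGlyph(f"{sg.id}_text", sg.id, s.name or s.id, replace_box(sg.bounding_box))
        )

    for r in network.reactions:
        rg = ReactionGlyph(f"{r.id}_glyph", r.id, BoundingBox(Point(0, 0), REACTION_W, REACTION_H))
        for k, p in enumerate(r.participants, start=1):
            rg.species_reference_glyphs.append(
                SpeciesReferenceGlyph(
                    f"{r.id}_srg_{k}", f"{p.species_id}_glyph", ROLE_MAP[p.role]
                )
            )
        layout.reaction_glyphs.append(rg)

    layout.validate()
    return layout


def replace_box(box: BoundingBox) -> BoundingBox:
    """Independent copy of a bounding box."""
    return BoundingBox(Point(box.position.x, box.position.y), box.width, box.height)


def create_alias(layout: Layout, reaction_id: str, species_id: str) -> SpeciesGlyph:
    """Add an alias glyph of ``species_id`` used exclusively by ``reaction_id``.

    All species-reference glyphs of that reaction that pointed at a glyph of
    the species are re-pointed to the new alias; other reactions keep their
    references.  Alias ids follow ``<speciesId>_alias_<n>`` in creation order.
    """
    rg = layout.get_reaction_glyph(reaction_id)
    species_glyph_ids = {g.id for g in layout.species_glyphs_of(species_id)}
    if not species_glyph_ids:
        raise LayoutError(f"species {species_id!r} has no glyph")
    hits = [srg for srg in rg.species_reference_glyphs if srg.species_glyph_id in species_glyph_ids]
    if not hits:
        raise LayoutError(
            f"species {species_id!r} is not a participant of reaction {reaction_id!r}"
        )
    n_alias = sum(1 for g in layout.species_glyphs if g.species_id == species_id and g.is_alias)
    original = layout.species_glyphs_of(species_id)[0]
    alias = SpeciesGlyph(
        f"{species_id}_alias_{n_alias + 1}",
        species_id,
        replace_box(original.bounding_box),
        is_alias=True,
    )
    layout.species_glyphs.append(alias)
    src_text = layout.text_glyphs_of(original.id)
    label = src_text[0].text if src_text else species_id
    layout.text_glyphs.append(
        TextGlyph(f"{alias.id}_text", alias.id, label, replace_box(alias.bounding_box))
    )
    for srg in hits:
        srg.species_glyph_id = alias.id
    layout.validate()
    return alias


def create_source_sink_glyph(layout: Layout, reaction_id: str, role: str) -> SpeciesGlyph:
    """Attach a source (role=substrate) or sink (role=product) pseudo-glyph.

    The glyph has no model species; under the SBGN template it renders as the
    empty-set symbol.
    """
    if role not in ("substrate", "product"):
        raise LayoutError("source/sink role must be 'substrate' or 'product'")
    rg = layout.get_reaction_glyph(reaction_id)
    n = sum(1 for g in layout.species_glyphs if g.species_id is None)
    glyph = SpeciesGlyph(
        f"emptyset_{n + 1}",
        None,
        BoundingBox(Point(0, 0), SOURCE_SINK_W, SOURCE_SINK_H),
    )
    layout.species_glyphs.append(glyph)
    k = len(rg.species_reference_glyphs) + 1
    rg.species_reference_glyphs.append(
        SpeciesReferenceGlyph(f"{reaction_id}_srg_{k}", glyph.id, role)
    )
    layout.validate()
    return glyph


def remove_species_glyph(layout: Layout, glyph_id: str) -> None:
    """Remove a species glyph together with its references and labels."""
    layout.get_species_glyph(glyph_id)  # raises KeyError if absent
    layout.species_glyphs = [g for g in layout.species_glyphs if g.id != glyph_id]
    for rg in layout.reaction_glyphs:
        rg.species_reference_glyphs = [
            srg for srg in rg.species_reference_glyphs if srg.species_glyph_id != glyph_id
        ]
    layout.text_glyphs = [t for t in layout.text_glyphs if t.target_glyph_id != glyph_id]
    layout.validate()


def glyph_boundary_anchor(box: BoundingBox, toward: Point, shape: str = "rectangle") -> Point:
    """Intersection of the ray (box center -> toward) with the box border.

    For ``shape="ellipse"`` the border is the inscribed ellipse.  If ``toward``
    lies inside the box the center is returned.
    """
    c = box.center
    d = toward - c
    if box.contains(toward) or (d.x == 0 and d.y == 0):
        return c
    hw, hh = box.width / 2, box.height / 2
    if shape == "ellipse":
        if hw == 0 or hh == 0:
            return c
        t = 1.0 / math.sqrt((d.x / hw) ** 2 + (d.y / hh) ** 2)
    else:
        tx = hw / abs(d.x) if d.x != 0 else math.inf
        ty = hh / abs(d.y) if d.y != 0 else math.inf
        t = min(tx, ty)
    return Point(c.x + d.x * t, c.y + d.y * t)
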