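"""Fluent user API: a network handle binding one model + one layout + one
render set, with element-list handles for batch styling and arrangement.

The surface follows the conventions of high-level pathway-visualization
scripting: ``load`` a model (toy grammar or SBML), select species/reactions,
batch-apply styles and arrangements, then ``draw`` or ``save``::

    net = netglyph.load(model_text)
    net.get_species_list(["Pyr"]).set_fill_colors("#FFEB3B")
    net.get_reaction("J1").align_vertical(center_at=(2200, 700), spread=800)
    net.draw("figure.svg")
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

logger = logging.getLogger("netglyph")

from . import arrange, autolayout, overlay, sbmlio
from .errors import LayoutError, NetglyphError, SBMLReadError
from .layout import (
    COMPARTMENT_MARGIN_FRAC,
    Layout,
    Point,
    SPECIES_W,
    create_alias,
    generate_layout,
)
from .model import Network, parse_model
from .style import (
    Ellipse,
    Rectangle,
    RenderInformation,
    apply_template,
    html_color,
    normalize_hex,
    set_group_attribute,
)

_SHAPE_NAMES = {
    "circle": lambda: [Ellipse()],
    "ellipse": lambda: [Ellipse()],
    "rectangle": lambda: [Rectangle(corner_rx=10.0, corner_ry=10.0)],
    "square": lambda: [Rectangle()],
}

DRAW_FORMATS = ("svg", "png", "pdf", "jpg")


def _as_color(value: str) -> str:
    """Accept hex strings or HTML color names."""
    try:
        return normalize_hex(value)
    except NetglyphError:
        return html_color(value)


@dataclass
class LabelHandle:
    handle: "NetworkHandle"
    target_glyph_id: str

    def _align(self, mode: str) -> "LabelHandle":
        arrange.align_label(self.handle.layout, self.target_glyph_id, mode)
        self.handle._log(f"align_label {self.target_glyph_id} {mode}")
        return self

    def align_to_vertical_center(self):
        return self._align("vertical_center")

    def align_to_horizontal_center(self):
        return self._align("horizontal_center")

    def align_to_top(self):
        return self._align("top")

    def align_to_bottom(self):
        return self._align("bottom")

    def align_to_left(self):
        return self._align("left")

    def align_to_right(self):
        return self._align("right")


@dataclass
class ElementListHandle:
    """Batch view over a list of glyph ids; every setter applies to all
    members and returns the handle for chaining."""

    handle: "NetworkHandle"
    glyph_ids: list[str]

    def _set(self, attribute: str, value) -> "ElementListHandle":
        set_group_attribute(self.handle.render, set(self.glyph_ids), attribute, value)
        self.handle._log(f"set {attribute} on {len(self.glyph_ids)} glyphs")
        return self

    def _text_ids(self) -> set[str]:
        ids = set()
        for gid in self.glyph_ids:
            ids.update(t.id for t in self.handle.layout.text_glyphs_of(gid))
        return ids

    # --- style setters ----------------------------------------------------

    def set_shapes(self, name: str) -> "ElementListHandle":
        try:
            shapes = _SHAPE_NAMES[name]()
        except KeyError:
            raise LayoutError(
                f"unknown shape {name!r}; expected one of {sorted(_SHAPE_NAMES)}"
            ) from None
        return self._set("shapes", shapes)

    def set_fill_colors(self, color: str) -> "ElementListHandle":
        return self._set("fill", _as_color(color))

    def set_colors(self, color: str) -> "ElementListHandle":
        return self._set("stroke", _as_color(color))

    def set_thicknesses(self, width: float) -> "ElementListHandle":
        return self._set("stroke_width", float(width))

    def set_font_sizes(self, size: float) -> "ElementListHandle":
        set_group_attribute(self.handle.render, self._text_ids(), "font_size", float(size))
        self.handle._log(f"set font_size on {len(self.glyph_ids)} glyph labels")
        return self

    def set_font_colors(self, color: str) -> "ElementListHandle":
        set_group_attribute(self.handle.render, self._text_ids(), "font_color", _as_color(color))
        self.handle._log(f"set font_color on {len(self.glyph_ids)} glyph labels")
        return self

    def switch_to_curve(self) -> "ElementListHandle":
        """Display reactions as bare curves (no center shape)."""
        return self._set("shapes", [])

    # --- geometry setters -------------------------------------------------

    def set_sizes(self, size: tuple[float, float]) -> "ElementListHandle":
        w, h = float(size[0]), float(size[1])
        if w <= 0 or h <= 0:
            raise LayoutError("glyph size must be positive")
        layout = self.handle.layout
        for gid in self.glyph_ids:
            g = layout.get_glyph(gid)
            c = g.bounding_box.center
            g.bounding_box.width = w
            g.bounding_box.height = h
            g.bounding_box.move_center_to(c)
        autolayout.reroute_references_to(layout, set(self.glyph_ids), set())
        self.handle._log(f"set size {w}x{h} on {len(self.glyph_ids)} glyphs")
        return self

    # --- arrangement ------------------------------------------------------

    def align_circle(
        self,
        center_at: tuple[float, float],
        radius: float,
        arc_start: float = 90.0,
        arc_end: float = -270.0,
    ) -> "ElementListHandle":
        layout = self.handle.layout
        reaction_ids = [
            rg.reaction_id for rg in layout.reaction_glyphs if rg.id in set(self.glyph_ids)
        ]
        if not reaction_ids:
            raise LayoutError("align_circle applies to reaction lists")
        spec = arrange.CircleSpec(
            Point(float(center_at[0]), float(center_at[1])), float(radius),
            float(arc_start), float(arc_end),
        )
        arrange.align_circle(layout, reaction_ids, spec)
        self.handle._log(f"align_circle {reaction_ids}")
        return self


@dataclass
class ReactionHandle:
    handle: "NetworkHandle"
    reaction_id: str

    @property
    def glyph(self):
        return self.handle.layout.get_reaction_glyph(self.reaction_id)

    def _axis(self, axis: str, center_at, spread) -> "ReactionHandle":
        spec = arrange.AxisSpec(
            axis, Point(float(center_at[0]), float(center_at[1])), float(spread)
        )
        arrange.align_axis(self.handle.layout, self.reaction_id, spec)
        self.handle._log(f"align_{axis} {self.reaction_id}")
        return self

    def align_vertical(self, center_at: tuple[float, float], spread: float):
        return self._axis("vertical", center_at, spread)

    def align_horizontal(self, center_at: tuple[float, float], spread: float):
        return self._axis("horizontal", center_at, spread)

    def get_label(self) -> LabelHandle:
        return LabelHandle(self.handle, self.glyph.id)

    def as_list(self) -> ElementListHandle:
        return ElementListHandle(self.handle, [self.glyph.id])


@dataclass
class CompartmentHandle:
    handle: "NetworkHandle"
    compartment_id: str

    @property
    def glyph(self):
        for cg in self.handle.layout.compartment_glyphs:
            if cg.compartment_id == self.compartment_id:
                return cg
        raise LayoutError(f"no glyph for compartment {self.compartment_id!r}")

    def set_font_color(self, color: str):
        ElementListHandle(self.handle, [self.glyph.id]).set_font_colors(color)
        return self

    def set_font_size(self, size: float):
        ElementListHandle(self.handle, [self.glyph.id]).set_font_sizes(size)
        return self

    def get_label(self) -> LabelHandle:
        return LabelHandle(self.handle, self.glyph.id)


@dataclass
class NetworkHandle:
    network: Network
    layout: Layout
    render: RenderInformation
    log: list[str] = field(default_factory=list)

    def _log(self, message: str) -> None:
        self.log.append(message)
        logger.debug(message)

    # --- selectors --------------------------------------------------------

    def get_species_list(self, ids: list[str] | None = None) -> ElementListHandle:
        """All glyphs (originals + aliases) of the given species; all species
        when ids is None."""
        if ids is None:
            glyphs = [g.id for g in self.layout.species_glyphs if g.species_id is not None]
        else:
            known = {s.id for s in self.network.species}
            bad = [i for i in ids if i not in known]
            if bad:
                raise LayoutError(f"unknown species: {', '.join(bad)}")
            glyphs = [
                g.id
                for g in self.layout.species_glyphs
                if g.species_id in set(ids)
            ]
        return ElementListHandle(self, glyphs)

    def get_reactions_list(self, ids: list[str] | None = None) -> ElementListHandle:
        if ids is None:
            glyphs = [g.id for g in self.layout.reaction_glyphs]
        else:
            known = {r.id for r in self.network.reactions}
            bad = [i for i in ids if i not in known]
            if bad:
                raise LayoutError(f"unknown reactions: {', '.join(bad)}")
            wanted = set(ids)
            glyphs = [g.id for g in self.layout.reaction_glyphs if g.reaction_id in wanted]
        return ElementListHandle(self, glyphs)

    def get_reaction(self, reaction_id: str) -> ReactionHandle:
        self.layout.get_reaction_glyph(reaction_id)  # raises naming the id
        return ReactionHandle(self, reaction_id)

    def get_compartment(self, compartment_id: str | None = None) -> CompartmentHandle:
        if compartment_id is None:
            compartment_id = self.network.compartments[0][0]
        if compartment_id not in {c for c, _ in self.network.compartments}:
            raise LayoutError(f"unknown compartment {compartment_id!r}")
        return CompartmentHandle(self, compartment_id)

    # --- mutations --------------------------------------------------------

    def create_aliases(self, mapping: dict[str, list[str]]) -> "NetworkHandle":
        """Per-reaction alias glyphs, e.g. ``{"J2": ["CoA"]}``."""
        for rid, species_ids in mapping.items():
            for sid in species_ids:
                create_alias(self.layout, rid, sid)
                self._log(f"alias {sid} for {rid}")
        return self

    def set_size(self, size: tuple[float, float]) -> "NetworkHandle":
        """Set the canvas dimensions; compartment glyphs track the canvas
        minus the standard margin."""
        w, h = float(size[0]), float(size[1])
        if w <= 0 or h <= 0:
            raise LayoutError("canvas size must be positive")
        self.layout.width, self.layout.height = w, h
        m = COMPARTMENT_MARGIN_FRAC
        for cg in self.layout.compartment_glyphs:
            old_center = cg.bounding_box.center
            cg.bounding_box.position = Point(w * m, h * m)
            cg.bounding_box.width = w * (1 - 2 * m)
            cg.bounding_box.height = h * (1 - 2 * m)
            dx = cg.bounding_box.center.x - old_center.x
            dy = cg.bounding_box.center.y - old_center.y
            for t in self.layout.text_glyphs_of(cg.id):
                t.bounding_box.position = Point(
                    t.bounding_box.position.x + dx, t.bounding_box.position.y + dy
                )
        self._log(f"set_size {w}x{h}")
        return self

    def apply_style_template(self, name: str) -> "NetworkHandle":
        self.render = apply_template(self.layout, name)
        self._log(f"template {name}")
        return self

    def apply_overlay(self, spec: overlay.OverlaySpec) -> "NetworkHandle":
        overlay.apply_overlay(self.layout, self.render, spec)
        self._log(f"overlay {spec.mode} on {len(spec.values)} elements")
        return self

    def add_color_bar(self, cmap, vmin, vmax, n_ticks, box) -> "NetworkHandle":
        overlay.add_color_bar(self.layout, self.render, cmap, vmin, vmax, n_ticks, box)
        self._log("color bar added")
        return self

    # --- output -----------------------------------------------------------

    def to_sbml(self) -> str:
        return sbmlio.write_sbml(self.network, self.layout, self.render)

    def to_svg(self) -> str:
        from .svg import export_svg

        return export_svg(self.layout, self.render)

    def draw(self, path: str) -> str:
        """Write the figure; the format dispatches on the file extension."""
        ext = path.rsplit(".", 1)[-1].lower() if "." in path else ""
        if ext == "svg":
            with open(path, "w") as fh:
                fh.write(self.to_svg())
        elif ext in ("png", "pdf", "jpg", "jpeg"):
            from .raster import render_to_file

            render_to_file(self.layout, self.render, path)
        else:
            raise LayoutError(
                f"unsupported output format {ext!r}; expected one of {DRAW_FORMATS}"
            )
        self._log(f"draw {path}")
        return path

    def save(self, path: str) -> str:
        """Write the unified SBML document (model + layout + render)."""
        try:
            with open(path, "w") as fh:
                fh.write(self.to_sbml())
        except OSError as exc:
            raise NetglyphError(f"cannot write {path}: {exc}") from exc
        self._log(f"save {path}")
        return path

    def validate(self) -> None:
        self.network.validate()
        self.layout.validate()
        self.render.validate()


DEFAULT_CANVAS = (1000.0, 1000.0)


def _autolayout_padding(w: float, h: float) -> float:
    # keep whole default-size glyphs inside the compartment box
    return COMPARTMENT_MARGIN_FRAC * min(w, h) + SPECIES_W / 2 + 5.0


def read_config(path: str) -> dict[str, float]:
    """``key = value`` configuration for auto-layout/arrangement constants
    (lines starting with '#' are comments)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = float(value.strip())
    return out


def load(
    source: str,
    *,
    canvas: tuple[float, float] = DEFAULT_CANVAS,
    template: str = "default",
    seed: int = 0,
    autolayout_params: autolayout.AutoLayoutParams | None = None,
) -> NetworkHandle:
    """Load a model (toy grammar text, SBML text, or a path to either) and
    return a fully visualizable handle.

    Sources lacking layout/render data get generated glyphs, a seeded
    force-directed placement with routed curves, and the named style template;
    existing layout/render data is preserved untouched.
    """
    text = source
    if "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()

    stripped = text.lstrip()
    if stripped.startswith("<"):
        network, layout, render = sbmlio.read_sbml(text)
    else:
        try:
            network = parse_model(text)
            layout = render = None
        except NetglyphError as model_err:
            try:
                network, layout, render = sbmlio.read_sbml(text)
            except SBMLReadError as sbml_err:
                raise NetglyphError(
                    f"source is neither model text ({model_err}) nor SBML ({sbml_err})"
                ) from None

    if layout is None:
        layout = generate_layout(network, canvas)
        params = autolayout_params or autolayout.AutoLayoutParams(
            seed=seed, padding=_autolayout_padding(*canvas)
        )
        autolayout.force_directed_layout(layout, params)
        autolayout.route_reaction_curves(layout)
    else:
        positioned = any(
            g.bounding_box.position.x != 0 or g.bounding_box.position.y != 0
            for g in layout.all_glyphs()
        )
        if not positioned and (layout.species_glyphs or layout.reaction_glyphs):
            params = autolayout_params or autolayout.AutoLayoutParams(
                seed=seed, padding=_autolayout_padding(layout.width, layout.height)
            )
            autolayout.force_directed_layout(layout, params)
            autolayout.route_reaction_curves(layout)
    if render is None:
        render = apply_template(layout, template)

    handle = NetworkHandle(network, layout, render)
    handle._log("loaded")
    handle.validate()
    return handle
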