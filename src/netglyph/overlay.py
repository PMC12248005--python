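"""Map simulation values (reaction fluxes, species concentrations) onto the
diagram as colors or sizes, plus a color-bar legend built from ordinary
layout/render glyphs so it survives SBML round-trips.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

from .autolayout import reroute_references_to
from .errors import LayoutError, StyleError
from .layout import BoundingBox, GraphicalObjectGlyph, Layout, Point, TextGlyph
from .style import RenderInformation, normalize_hex, set_group_attribute

#: default flux colormap: muted gray for low values, vivid orange-red for high
DEFAULT_FLUX_STOPS = [(0.0, "#C8C8C8"), (1.0, "#FF4500")]

COLORBAR_SEGMENTS = 32


@dataclass
class ColorMap:
    stops: list[tuple[float, str]] = field(default_factory=lambda: list(DEFAULT_FLUX_STOPS))
    name: str = "flux"

    def __post_init__(self):
        if len(self.stops) < 2:
            raise ValueError("colormap needs at least 2 stops")
        fracs = [f for f, _ in self.stops]
        if fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValueError("colormap stops must start at 0 and end at 1")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("colormap fractions must be strictly increasing")
        self.stops = [(f, normalize_hex(c)) for f, c in self.stops]


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def value_to_color(v: float, vmin: float, vmax: float, cmap: ColorMap) -> str:
    """Linear sRGB interpolation between the bracketing colormap stops.

    The value is clamped into [vmin, vmax]; channels round half-up.
    """
    if vmin > vmax:
        raise ValueError("vmin must not exceed vmax")
    if vmin == vmax:
        f = 0.5  # degenerate range: neutral midpoint
    else:
        f = min(max((v - vmin) / (vmax - vmin), 0.0), 1.0)
    stops = cmap.stops
    for (f0, c0), (f1, c1) in zip(stops, stops[1:]):
        if f <= f1 or (f1, c1) == stops[-1]:
            if f <= f0:
                return c0
            t = (f - f0) / (f1 - f0)
            r0, g0, b0 = _hex_to_rgb(c0)
            r1, g1, b1 = _hex_to_rgb(c1)
            rgb = (
                _round_half_up(r0 + t * (r1 - r0)),
                _round_half_up(g0 + t * (g1 - g0)),
                _round_half_up(b0 + t * (b1 - b0)),
            )
            return "#%02X%02X%02X" % rgb
    return stops[-1][1]


@dataclass
class OverlaySpec:
    values: dict[str, float]
    mode: str = "color"  # "color" | "size"
    vmin: float | None = None  # default: data minimum
    vmax: float | None = None  # default: data maximum
    colormap: ColorMap = field(default_factory=ColorMap)
    size_range: tuple[float, float] = (4.0, 40.0)

    def __post_init__(self):
        if self.mode not in ("color", "size"):
            raise ValueError("mode must be 'color' or 'size'")
        if not self.values:
            raise ValueError("overlay needs at least one value")

    def range(self) -> tuple[float, float]:
        lo = self.vmin if self.vmin is not None else min(self.values.values())
        hi = self.vmax if self.vmax is not None else max(self.values.values())
        if lo > hi:
            raise ValueError("vmin must not exceed vmax")
        return lo, hi

    def fraction(self, v: float) -> float:
        lo, hi = self.range()
        if lo == hi:
            return 0.5
        return min(max((v - lo) / (hi - lo), 0.0), 1.0)


def _target_glyphs(layout: Layout, element_id: str):
    """All glyphs an element id maps to: a reaction glyph (plus its curve
    references, restyled through the parent id) or the species glyphs
    (original + aliases) of a species."""
    for rg in layout.reaction_glyphs:
        if rg.reaction_id == element_id:
            return "reaction", [rg]
    sgs = layout.species_glyphs_of(element_id)
    if sgs:
        return "species", sgs
    return None, []


def apply_overlay(layout: Layout, render: RenderInformation, spec: OverlaySpec) -> RenderInformation:
    """Encode the values onto the targeted elements.

    color mode: reaction fluxes recolor curve strokes, species concentrations
    recolor node fills.  size mode: fluxes set curve stroke widths, species
    values rescale node boxes about their centers (aspect preserved; affected
    curves re-routed).  Elements missing from ``values`` keep their template
    style — absence of data is not zero.
    """
    missing = [eid for eid in spec.values if _target_glyphs(layout, eid)[0] is None]
    if missing:
        raise LayoutError(f"overlay ids resolve to no glyph: {', '.join(sorted(missing))}")
    lo, hi = spec.range()
    smin, smax = spec.size_range
    moved: set[str] = set()
    for eid in spec.values:  # dict order: deterministic and caller-controlled
        v = spec.values[eid]
        kind, glyphs = _target_glyphs(layout, eid)
        f = spec.fraction(v)
        if spec.mode == "color":
            color = value_to_color(v, lo, hi, spec.colormap) if lo != hi else value_to_color(
                0.5, 0.0, 1.0, spec.colormap
            )
            attr = "stroke" if kind == "reaction" else "fill"
            set_group_attribute(render, {g.id for g in glyphs}, attr, color)
        else:
            if kind == "reaction":
                width = smin + f * (smax - smin)
                set_group_attribute(render, {g.id for g in glyphs}, "stroke_width", width)
            else:
                for g in glyphs:
                    new_w = smin + f * (smax - smin)
                    scale = new_w / g.bounding_box.width if g.bounding_box.width else 1.0
                    new_h = g.bounding_box.height * scale
                    c = g.bounding_box.center
                    g.bounding_box.width = new_w
                    g.bounding_box.height = new_h
                    g.bounding_box.move_center_to(c)
                    moved.add(g.id)
    if moved:
        reroute_references_to(layout, moved, set())
    return render


def read_value_table(path: str) -> dict[str, float]:
    """Two-column id,value CSV/TSV (header row optional, delimiter sniffed)."""
    values: dict[str, float] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        for row in csv.reader(fh, delimiter=delim):
            if not row or not row[0].strip():
                continue
            try:
                values[row[0].strip()] = float(row[1])
            except (IndexError, ValueError):
                continue  # header or malformed row
    if not values:
        raise StyleError(f"no id,value rows found in {path}")
    return values


def add_color_bar(
    layout: Layout,
    render: RenderInformation,
    cmap: ColorMap,
    vmin: float,
    vmax: float,
    n_ticks: int,
    box: BoundingBox,
    n_segments: int = COLORBAR_SEGMENTS,
) -> tuple[Layout, RenderInformation]:
    """Append a color-bar legend: ``n_segments`` stacked rectangles filling
    ``box`` (top = vmax) and ``n_ticks`` numeric labels.

    All appended glyphs carry ids prefixed ``colorbar_`` and are ordinary
    layout/render elements, so they survive SBML round-trips.  Re-adding a
    color bar replaces the previous one.
    """
    if n_ticks < 2:
        raise LayoutError("color bar needs at least 2 ticks")
    if box.width <= 0 or box.height <= 0:
        raise LayoutError("color-bar box must have positive area")

    remove_color_bar(layout, render)

    seg_h = box.height / n_segments
    for i in range(n_segments):
        gid = f"colorbar_seg_{i + 1:03d}"
        seg_box = BoundingBox(
            Point(box.position.x, box.position.y + i * seg_h), box.width, seg_h
        )
        layout.graphical_objects.append(GraphicalObjectGlyph(gid, seg_box))
        f_mid = 1.0 - (i + 0.5) / n_segments  # top segment ~ vmax
        v = vmin + f_mid * (vmax - vmin)
        color = value_to_color(v, vmin, vmax, cmap) if vmin != vmax else value_to_color(
            0.5, 0.0, 1.0, cmap
        )
        set_group_attribute(render, {gid}, "fill", color)
        set_group_attribute(render, {gid}, "stroke", "none")

    label_h = 16.0
    for j in range(n_ticks):
        frac = j / (n_ticks - 1)  # 0 = top = vmax
        v = vmax + frac * (vmin - vmax)
        y = box.position.y + frac * box.height - label_h / 2
        layout.text_glyphs.append(
            TextGlyph(
                f"colorbar_tick_{j + 1:02d}",
                f"colorbar_seg_{max(1, min(n_segments, int(frac * n_segments) + 1)):03d}",
                "%.3g" % v,
                BoundingBox(Point(box.position.x + box.width + 6.0, y), 48.0, label_h),
            )
        )
    layout.validate()
    return layout, render


def remove_color_bar(layout: Layout, render: RenderInformation) -> None:
    """Drop all color-bar glyphs and their id-list styles."""
    layout.text_glyphs = [t for t in layout.text_glyphs if not t.id.startswith("colorbar_")]
    layout.graphical_objects = [
        g for g in layout.graphical_objects if not g.id.startswith("colorbar_")
    ]
    render.styles = [
        s
        for s in render.styles
        if not (s.id_list and all(i.startswith("colorbar_") for i in s.id_list))
    ]
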