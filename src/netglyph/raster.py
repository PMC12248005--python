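"""Raster/vector output backend (PNG, PDF, JPEG) built on matplotlib.

SVG is the only format with byte-exact guarantees (see :mod:`netglyph.svg`);
this backend redraws the same resolved scene with matplotlib artists and lets
its writers produce the requested format.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
from matplotlib.path import Path as MplPath

from .errors import LayoutError
from .layout import Layout
from .style import (
    CurvePrimitive,
    Ellipse,
    Polygon,
    Rectangle,
    RenderInformation,
    resolve_color,
    resolve_style,
)

_PT_PER_UNIT = 72.0 / 100.0  # canvas units are treated as ~pixels at 100 dpi


def _mpl_color(c: str | None):
    if c is None or c == "none":
        return "none"
    return c


def _add_shape(ax, shape, box, fill, stroke, sw):
    x, y, w, h = box.position.x, box.position.y, box.width, box.height
    kw = dict(facecolor=_mpl_color(fill), edgecolor=_mpl_color(stroke), linewidth=sw * 0.5)
    if isinstance(shape, Rectangle):
        r = min(shape.corner_rx / 100.0 * w, shape.corner_ry / 100.0 * h)
        if r > 0:
            ax.add_patch(
                mpatches.FancyBboxPatch(
                    (x + r, y + r), w - 2 * r, h - 2 * r,
                    boxstyle=f"round,pad={r},rounding_size={r}", **kw,
                )
            )
        else:
            ax.add_patch(mpatches.Rectangle((x, y), w, h, **kw))
    elif isinstance(shape, Ellipse):
        ax.add_patch(mpatches.Ellipse((x + w / 2, y + h / 2), w, h, **kw))
    elif isinstance(shape, Polygon):
        pts = [(x + px / 100.0 * w, y + py / 100.0 * h) for px, py in shape.points]
        ax.add_patch(mpatches.Polygon(pts, closed=True, **kw))
    elif isinstance(shape, CurvePrimitive):
        pts = [(x + px / 100.0 * w, y + py / 100.0 * h) for px, py in shape.points]
        ax.plot(*zip(*pts), color=_mpl_color(stroke), linewidth=sw * 0.5)


def render_to_file(layout: Layout, render: RenderInformation, path: str) -> None:
    """Draw the scene and save it; format dispatches on the file extension."""
    ext = path.rsplit(".", 1)[-1].lower()
    if ext not in ("png", "pdf", "jpg", "jpeg"):
        raise LayoutError(f"unsupported raster format {ext!r}")

    fig, ax = plt.subplots(figsize=(layout.width / 100.0, layout.height / 100.0), dpi=100)
    try:
        ax.set_xlim(0, layout.width)
        ax.set_ylim(layout.height, 0)  # y-down canvas frame
        ax.set_aspect("equal")
        ax.axis("off")
        fig.subplots_adjust(left=0, right=1, top=1, bottom=0)
        bg = resolve_color(render, render.background) or "#FFFFFF"
        ax.add_patch(
            mpatches.Rectangle((0, 0), layout.width, layout.height, facecolor=bg, zorder=-1)
        )

        for cg in layout.compartment_glyphs:
            g = resolve_style(render, cg)
            for shape in g.shapes or ():
                _add_shape(ax, shape, cg.bounding_box,
                           resolve_color(render, g.fill), resolve_color(render, g.stroke),
                           g.stroke_width or 0.0)

        for rg in layout.reaction_glyphs:
            for srg in rg.species_reference_glyphs:
                if not srg.curve:
                    continue
                g = resolve_style(render, srg, parent_reaction_glyph_id=rg.id)
                stroke = resolve_color(render, g.stroke) or "#000000"
                verts, codes = [], []
                for seg in srg.curve:
                    if not verts:
                        verts.append((seg.start.x, seg.start.y))
                        codes.append(MplPath.MOVETO)
                    if seg.kind == "cubic_bezier":
                        verts += [
                            (seg.base_point1.x, seg.base_point1.y),
                            (seg.base_point2.x, seg.base_point2.y),
                            (seg.end.x, seg.end.y),
                        ]
                        codes += [MplPath.CURVE4] * 3
                    else:
                        verts.append((seg.end.x, seg.end.y))
                        codes.append(MplPath.LINETO)
                ax.add_patch(
                    mpatches.PathPatch(
                        MplPath(verts, codes), facecolor="none", edgecolor=stroke,
                        linewidth=(g.stroke_width or 1.0) * 0.5,
                    )
                )
            g = resolve_style(render, rg)
            for shape in g.shapes if g.shapes is not None else ():
                _add_shape(ax, shape, rg.bounding_box,
                           resolve_color(render, g.fill), resolve_color(render, g.stroke),
                           g.stroke_width or 0.0)

        for sg in layout.species_glyphs:
            g = resolve_style(render, sg)
            for shape in g.shapes or ():
                _add_shape(ax, shape, sg.bounding_box,
                           resolve_color(render, g.fill), resolve_color(render, g.stroke),
                           g.stroke_width or 0.0)

        for go in layout.graphical_objects:
            g = resolve_style(render, go)
            for shape in g.shapes or ():
                _add_shape(ax, shape, go.bounding_box,
                           resolve_color(render, g.fill), resolve_color(render, g.stroke),
                           g.stroke_width or 0.0)

        for t in layout.text_glyphs:
            g = resolve_style(render, t)
            c = t.bounding_box.center
            ax.text(
                c.x, c.y, t.text, ha="center", va="center",
                fontsize=(g.font_size or 12.0) * _PT_PER_UNIT,
                color=resolve_color(render, g.font_color) or "#000000",
            )

        fig.savefig(path, format="jpeg" if ext == "jpg" else ext)
    finally:
        plt.close(fig)
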