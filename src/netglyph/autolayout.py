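"""Force-directed initial placement and Bézier routing of reaction curves.

The placement is a Fruchterman–Reingold force simulation over the bipartite
graph whose nodes are species-glyph centers and reaction centers and whose
edges are the species-reference glyphs.  With N nodes on a W x H canvas and
``k = k_scale * sqrt(W*H / N)``, each iteration applies

* a repulsive displacement of magnitude ``k^2 / d`` between every node pair at
  distance ``d`` (all pairs — no grid approximation; fixture-scale networks
  are small and approximations would silently change the math), and
* an attractive displacement of magnitude ``d^2 / k`` along every edge,

caps each node's net displacement at the current temperature, cools the
temperature linearly to zero over the iteration budget, and clamps nodes into
the canvas minus a padding strip.  Initial positions are drawn uniformly at
random from the padded canvas with a caller-supplied seed, so a run is fully
deterministic.

After placement, :func:`route_reaction_curves` gives every species-reference
glyph a curve: one cubic Bézier per substrate/product (tangent-aligned to the
reaction axis at the reaction center) and a straight line per modifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import LayoutError
from .layout import Layout, Point, cubic, glyph_boundary_anchor, line

#: minimum inter-node distance in force computations, to avoid singularities
MIN_DISTANCE = 1e-3


@dataclass
class AutoLayoutParams:
    k_scale: float = 1.0
    iterations: int = 100
    initial_temperature: float | None = None  # default: canvas_width / 10
    seed: int = 0
    padding: float = 10.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be > 0")


def _layout_nodes(layout: Layout) -> tuple[list[str], list[tuple[int, int]]]:
    """Node ids (species glyphs + reaction glyphs) and edge index pairs."""
    node_ids = [g.id for g in layout.species_glyphs] + [g.id for g in layout.reaction_glyphs]
    index = {gid: i for i, gid in enumerate(node_ids)}
    edges = []
    for rg in layout.reaction_glyphs:
        for srg in rg.species_reference_glyphs:
            edges.append((index[rg.id], index[srg.species_glyph_id]))
    return node_ids, edges


def force_directed_layout(
    layout: Layout, params: AutoLayoutParams | None = None
) -> Layout:
    """Place species and reaction glyphs with the force simulation (in place).

    Returns the same layout for chaining.  Bit-for-bit deterministic for a
    fixed seed.
    """
    positions, node_ids, _ = _simulate(layout, params or AutoLayoutParams())
    for gid, (x, y) in zip(node_ids, positions):
        layout.move_glyph_center(gid, Point(float(x), float(y)))
    return layout


def displacement_history(layout: Layout, params: AutoLayoutParams | None = None) -> np.ndarray:
    """Per-iteration sums of applied node-displacement magnitudes (an energy
    proxy: it shrinks as the simulation settles)."""
    _, _, history = _simulate(layout, params or AutoLayoutParams())
    return history


def _simulate(layout: Layout, params: AutoLayoutParams):
    W, H = layout.width, layout.height
    if W <= 0 or H <= 0:
        raise LayoutError("canvas must have positive area")
    node_ids, edges = _layout_nodes(layout)
    n = len(node_ids)
    history = np.zeros(params.iterations)
    if n == 0:
        return np.zeros((0, 2)), node_ids, history

    pad = min(params.padding, W / 2, H / 2)
    rng = np.random.default_rng(params.seed)
    pos = np.column_stack(
        [rng.uniform(pad, W - pad, size=n), rng.uniform(pad, H - pad, size=n)]
    )
    if n == 1:
        return pos, node_ids, history

    k = params.k_scale * math.sqrt(W * H / n)
    t0 = params.initial_temperature if params.initial_temperature is not None else W / 10
    e_idx = np.array(edges, dtype=int) if edges else np.zeros((0, 2), dtype=int)

    for it in range(params.iterations):
        delta = pos[:, None, :] - pos[None, :, :]  # delta[i,j] = pos_i - pos_j
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, MIN_DISTANCE)
        # repulsion: push i away from every j with magnitude k^2/d
        coeff = (k * k) / (dist * dist)  # (k^2/d) / d, applied to the raw delta
        np.fill_diagonal(coeff, 0.0)
        disp = (delta * coeff[:, :, None]).sum(axis=1)
        # attraction along edges: pull endpoints together with magnitude d^2/k
        if len(e_idx):
            a, b = e_idx[:, 0], e_idx[:, 1]
            ed = pos[a] - pos[b]
            edist = np.maximum(np.linalg.norm(ed, axis=1), MIN_DISTANCE)
            pull = ed * (edist / k)[:, None]  # (d^2/k) * unit vector
            np.subtract.at(disp, a, pull)
            np.add.at(disp, b, pull)
        # cap at current temperature (linear cooling to zero)
        t = t0 * (1.0 - it / params.iterations)
        mag = np.maximum(np.linalg.norm(disp, axis=1), 1e-12)
        step = disp * (np.minimum(mag, t) / mag)[:, None]
        pos += step
        pos[:, 0] = np.clip(pos[:, 0], pad, W - pad)
        pos[:, 1] = np.clip(pos[:, 1], pad, H - pad)
        history[it] = np.linalg.norm(step, axis=1).sum()

    return pos, node_ids, history


# --- curve routing ---------------------------------------------------------


def _check_positioned(layout: Layout) -> None:
    for g in layout.all_glyphs():
        p = g.bounding_box.position
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            raise LayoutError(f"glyph {g.id!r} is not positioned")


def reaction_axis(layout: Layout, rg) -> Point:
    """Unit vector from the reactant-centroid to the product-centroid; +x when
    degenerate."""
    subs = [s for s in rg.species_reference_glyphs if s.role in ("substrate", "sidesubstrate")]
    prods = [s for s in rg.species_reference_glyphs if s.role in ("product", "sideproduct")]

    def centroid(srgs):
        pts = [layout.get_species_glyph(s.species_glyph_id).bounding_box.center for s in srgs]
        if not pts:
            return None
        return Point(sum(p.x for p in pts) / len(pts), sum(p.y for p in pts) / len(pts))

    cs, cp = centroid(subs), centroid(prods)
    if cs is None or cp is None:
        return Point(1.0, 0.0)
    d = cp - cs
    n = d.norm()
    if n < 1e-12:
        return Point(1.0, 0.0)
    return Point(d.x / n, d.y / n)


def route_srg(layout: Layout, rg, srg, axis: Point | None = None) -> None:
    """Standard routing for one species-reference glyph (in place)."""
    if axis is None:
        axis = reaction_axis(layout, rg)
    center = rg.center
    sg = layout.get_species_glyph(srg.species_glyph_id)
    anchor = glyph_boundary_anchor(sg.bounding_box, center)
    if srg.role == "modifier":
        end = glyph_boundary_anchor(rg.bounding_box, sg.bounding_box.center)
        srg.curve = [line(anchor, end)]
        layout.custom_curves.discard(srg.id)
        return
    if srg.role in ("substrate", "sidesubstrate"):
        start, end = anchor, center
        chord = end - start
        L = chord.norm()
        bp1 = start + chord.scaled(1 / 3)
        bp2 = end - axis.scaled(L / 3)
    else:  # product-side
        start, end = center, anchor
        chord = end - start
        L = chord.norm()
        bp1 = start + axis.scaled(L / 3)
        bp2 = end - chord.scaled(1 / 3)
    srg.curve = [cubic(start, end, bp1, bp2)]
    layout.custom_curves.discard(srg.id)


def route_reaction_curves(layout: Layout, reaction_ids: list[str] | None = None) -> Layout:
    """Assign species-reference glyphs their curves (in place).

    Substrates: cubic from the species boundary anchor to the reaction center;
    products: cubic from the reaction center out to the species boundary
    anchor.  Base points sit at 1/3 and 2/3 of the chord, with the
    center-side base point displaced onto the reaction axis so the curve
    leaves/enters the center tangent to the axis.  Modifiers get a straight
    line ending on the reaction bounding-box border.  When ``reaction_ids`` is
    given only those reactions are routed.
    """
    _check_positioned(layout)
    wanted = None if reaction_ids is None else set(reaction_ids)
    for rg in layout.reaction_glyphs:
        if wanted is not None and rg.reaction_id not in wanted:
            continue
        axis = reaction_axis(layout, rg)
        for srg in rg.species_reference_glyphs:
            route_srg(layout, rg, srg, axis)
    return layout


def reroute_references_to(layout: Layout, glyph_ids: set[str], skip_reactions: set[str]) -> None:
    """Re-route the curves of every reaction touching one of the moved
    species glyphs.

    The whole reaction is re-routed — its axis depends on all participant
    positions, so sibling curves must stay consistent — except for curves an
    arrangement operator shaped explicitly (``layout.custom_curves``)."""
    for rg in layout.reaction_glyphs:
        if rg.reaction_id in skip_reactions:
            continue
        touched = any(
            srg.species_glyph_id in glyph_ids and srg.curve
            for srg in rg.species_reference_glyphs
        )
        if not touched:
            continue
        axis = reaction_axis(layout, rg)
        for srg in rg.species_reference_glyphs:
            if srg.id not in layout.custom_curves:
                route_srg(layout, rg, srg, axis)
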