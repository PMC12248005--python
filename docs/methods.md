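# Methods

This note documents the geometric and stylistic conventions netglyph commits
to, the parameters that matter, and the boundaries of what the test suite
demonstrates.

## Coordinate frame and angle convention

All geometry uses the SBML Layout frame: real-valued canvas units, origin at
the top-left, y increasing downward. Arrangement angles are degrees in the
mathematical (counter-clockwise) sense mapped into this frame,

    x = cx + r·cos θ,    y = cy − r·sin θ,

so θ = 90° is "up" on screen and a negative angular step advances clockwise.
This convention makes a circle specified as `arc_start=105, arc_end=−255`
(span −360°, endpoint-exclusive) place n = 8 reactions exactly 45° apart with
the first at the upper left — the layout a biochemist expects of a cycle
diagram. Pixel identity with any other tool is not claimed; the convention
itself is the contract, and an inverse-trigonometric oracle
(`arrange.recover_angle`) closes the loop in tests.

## Model grammar

The parser accepts the small Antimony-like subset sufficient for toy models:
irreversible reaction lines `ID: term (+ term)* -> term (+ term)*;` with
optional positive coefficients, plus one `default_compartment is "Name";`
statement. Both straight and typographic quotes are accepted because
published listings routinely carry typographic quotes. Modifiers exist in the
data model (they arrive via SBML input) but have no grammar syntax. The
grammar writer (`serialize_model`) is an exact inverse on networks in the
grammar's normal form — species ordered by first appearance, every species
used; networks outside that form survive as a semantic (reactions +
used-species) round trip.

## Force-directed placement

The auto-layout is a Fruchterman–Reingold simulation on the bipartite node
set {species glyph centers} ∪ {reaction centers} with one edge per
species-reference glyph. Parameters (`AutoLayoutParams`):

| parameter | default | meaning |
|---|---|---|
| `k_scale` | 1.0 | scales the ideal edge length k = k_scale·√(W·H/N) |
| `iterations` | 100 | cooling schedule length |
| `initial_temperature` | W/10 | per-iteration displacement cap, decays linearly to 0 |
| `seed` | required | seeds the uniform initial positions (deterministic runs) |
| `padding` | 10 | clamp margin inside the canvas, in canvas units |

Repulsion is computed between **all** node pairs (no grid approximation):
fixture-scale networks are small, and an approximation would be silently
different mathematics rather than an optimization. Inter-node distances are
floored at 10⁻³ canvas units to avoid singularities. Alias glyphs participate
as independent nodes — separating cofactor copies is their purpose. Two
closed-form properties anchor the implementation: a two-node system
equilibrates where k²/d = d²/k, i.e. d = k (verified to 5%), and a three-node
path straightens to a collinearity defect below 0.05·k.

`load()` widens the padding to the compartment margin plus half a default
glyph so freshly placed glyphs land inside the compartment box.

## Curve routing

Every substrate/product reference gets one cubic Bézier between the species
glyph's boundary anchor (ray–box intersection toward the reaction center) and
the reaction center. Base points sit at 1/3 and 2/3 of the chord, with the
center-side base point moved onto the reaction axis — the unit vector from
the reactant centroid to the product centroid (+x when degenerate) — so
curves leave/enter the center tangent to the axis. Modifiers get a straight
line ending on the reaction box border. Circle alignment replaces the main
substrate/product curves with segments whose base points lie **on** the
circle at interpolated angles, so the backbone visibly bends along the arc.

When an operation moves glyphs, every reaction touching a moved glyph is
re-routed as a whole (the axis is shared state), except curves explicitly
shaped by an arrangement operator, which are tracked in a session-only set
and preserved.

## Arrangement

Circle alignment spaces n reactions by span/n on a full 360° span
(endpoint-exclusive) and span/(n−1) otherwise. Each reaction's **main**
substrate and product are placed on the circle at ∓0.4·step around it; the
main participant is the glyph with the highest species-reference degree
across all reactions (ties broken by declaration order) — a backbone
metabolite beats a cofactor whose other uses were aliased away, which is what
makes Pyr→AcCoA the spine of the TCA example without user hints. Side species
exclusive to the reaction (degree 1) go radially inside (substrates) or
outside (products) at 0.18·r; axial alignment puts them laterally at
0.35·spread. These three fractions are package constants exposed as keyword
arguments; whether side species belong inside or outside the circle is a
documented choice, not a standard. All placement is absolute (computed from
the spec alone), which is what makes every operator idempotent.

## Style resolution

Styles address glyphs by type list, role list and/or id list, as in SBML
Render. Because Render permits overlapping styles without defining
precedence, netglyph commits to a deterministic cascade: type-tier styles
apply first, then role-tier, then id-tier, later-defined styles winning
within a tier, and a complete built-in default group backstops everything —
resolution is total and pure. A species-reference glyph additionally matches
id styles aimed at its parent reaction glyph, so batch edits on reactions
restyle their curves. Head attributes use `"none"` (explicitly headless,
serializable) distinct from unset. Template constants (Escher stroke width
18, SBGN process squares, arrowhead geometries) are this package's
approximations — the Escher interchange format itself carries no styling —
and every attribute is overridable.

## Data overlays

`value_to_color` clamps v into [vmin, vmax], locates the bracketing colormap
stops and interpolates each sRGB channel linearly, rounding half-up; channel
monotonicity therefore follows from monotone stops. Degenerate ranges
(vmin = vmax, or all values equal) map everything to the fraction 0.5 — a
neutral midpoint rather than a division by zero. Elements absent from the
value table keep their template style: absence of data is not zero flux. The
default flux map runs muted gray `#C8C8C8` → vivid orange-red `#FF4500`. The
color bar is 32 stacked solid rectangles plus `%.3g` tick labels, built from
ordinary layout/render glyphs (ids prefixed `colorbar_`) precisely so that it
persists inside the SBML document without requiring gradient-paint support in
consumers; re-adding a bar replaces the previous one.

## SBML serialization

Documents are SBML L3V1 with layout v1 and render v1, render information
local to the layout (the widest-consumer choice). The writer is canonical:
fixed element order and 6-decimal fixed-point numbers with trailing zeros
trimmed, so identical state yields byte-identical text and
`write ∘ read ∘ write = write` exactly; in-memory coordinates round-trip to
that 6-decimal grid. On reading, species glyphs beyond the first for a given
species are flagged as aliases, and glyphs with no species attribute become
source/sink pseudo-glyphs. Two attributes ride in a small extension namespace
because Render has no standard slot for them: a font color distinct from the
shape stroke, and the marker distinguishing "explicitly no shapes"
(curve-only reaction display) from "shapes unset". Consumers ignoring unknown
attributes see plain Layout/Render data.

Document validation is structural — well-formed XML, required core
attributes, resolvable cross-references, declared package namespaces —
implemented in `validate_document` and exercised together with the
read/write identity property.

## Synthetic data

`generate_random_network(n_species, n_reactions, seed)` produces topological
fixtures: each reaction draws 1–3 reactants and 1–3 products, disjoint within
a reaction (no self-loops), deterministically per seed. Test sizes (≤ ~12
species, ≤ ~8 reactions, 20 seeds for round-trip sweeps) were chosen as the
scale at which every code path is exercised while the whole suite stays
interactive. What these fixtures do *not* emulate: realistic degree
distributions (hub metabolites), compartmentalized topologies, modifiers, or
curated aesthetics — so passing tests demonstrate correctness of the geometry
and serialization contracts, not figure quality on genome-scale models. The
TCA worked example is the curated end-to-end case.

## Known limitations

- Layout: no orthogonal/layered routing, no edge-crossing minimization, no
  overlap resolution after arrangement; compartments constrain placement only
  through the initial clamp.
- Render: solid colors only (no gradient paints), one shape list + label set
  per element, SBGN coverage limited to the process-description glyphs the
  templates use.
- I/O: no SBML L2 layout annotations, no global render lists, no SBGN-ML.
  PNG/PDF/JPEG are backend renderings without byte-exactness guarantees.
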