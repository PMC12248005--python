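# netglyph

Standards-based visualization of biochemical reaction networks in Python.

Most pathway-drawing tools keep their visual data in tool-specific formats,
divorced from the model itself. netglyph instead generates and manipulates the
**SBML Level 3 Layout and Render packages**, so a network's geometry (glyph
positions, Bézier reaction curves) and styling (colors, shapes, fonts,
arrowheads) live in the *same file* as the model, readable by any
standards-aware consumer. It is aimed at systems-biology modelers who want
reproducible, scriptable figures of their SBML models.

## What it does

- **Automatic glyph generation** — one species/reaction/compartment/text glyph
  per model element, alias glyphs for ubiquitous cofactors, and source/sink
  (∅) pseudo-glyphs with no model counterpart.
- **Force-directed auto-layout** — a Fruchterman–Reingold simulation over the
  bipartite species/reaction graph. With N nodes on a W×H canvas and
  k = k_scale·√(WH/N), every node pair repels with magnitude k²/d and every
  species-reference edge attracts with d²/k; displacements are capped by a
  temperature that cools linearly to zero. Curves are then routed as cubic
  Béziers that enter/leave each reaction center tangent to the reaction axis.
- **Arrangement operators** — place chosen reactions on circles/arcs or
  vertical/horizontal axes (the way TCA-cycle or glycolysis wall charts are
  drawn), with main substrate/product selection by glyph-graph degree and
  label alignment helpers.
- **Style system** — SBML-Render-shaped styles resolved through a
  deterministic cascade (type < role < id, later wins within a tier), the 148
  HTML/CSS named colors, and predefined templates: `default`, `sbgn`
  (process-diagram idiom: process nodes, headless consumption arcs, ∅ symbol)
  and `escher` (thick curves, circular metabolites, bold labels).
- **Data overlays** — map reaction fluxes / species concentrations onto curve
  color or thickness and node fill or size via piecewise-linear colormaps,
  plus a color-bar legend built from ordinary glyphs so it survives SBML
  round trips.
- **Output** — canonical SBML (byte-stable writer), deterministic SVG, and
  PNG/PDF/JPEG through a matplotlib backend.

## Worked example

The packaged demonstration arranges the TCA cycle: pyruvate dehydrogenase
(J1) vertically on top, the eight cycle reactions (J2..J9) on a circle of
radius 1500 centered at (2200, 2800), spanning the arc from 105° to −255°
(one 45° step per reaction, clockwise on screen).

```python
import netglyph

model = """
J1: Pyr + NAD + CoA -> CO2 + NADH + AcCoA;
J2: Oxalo + AcCoA + H2O -> CoA + Cit;
...
default_compartment is "TCA Cycle";
"""

net = netglyph.load(model)
net.create_aliases({"J2": ["CoA"], "J9": ["NAD", "NADH"]})
net.get_species_list().set_shapes("circle")
net.get_reactions_list().set_thicknesses(22)
net.get_reactions_list(["J2", "J3", "J4", "J5", "J6", "J7", "J8", "J9"]).align_circle(
    center_at=(2200, 2800), radius=1500, arc_start=105, arc_end=-255
)
net.get_reaction("J1").align_vertical(center_at=(2200, 700), spread=800)
net.set_size((4500, 5000))
net.draw("TCA_Cycle.svg")
net.save("TCA_Cycle.xml")
```

The full script lives in `netglyph.examples.tca_pipeline()`. Checking the
placed geometry:

```
J2: center=(1811.8, 1351.1)  r=1500.0  theta=105.0 deg
J5: center=(3499.0, 3550.0)  r=1500.0  theta=-30.0 deg
J9: center=(901.0, 2050.0)  r=1500.0  theta=150.0 deg
```

Every aligned reaction center sits exactly 1500 canvas units from the circle
center; J2 opens the arc at 105° and each subsequent reaction steps −45°
(J9 at −255° ≡ 150°). J1's main substrate (Pyr) and product (AcCoA) end up at
(2200, 300) and (2200, 1100) — a vertical span of exactly the requested 800 —
and the saved SBML document declares the 4500 × 5000 canvas together with all
styling (yellow metabolites `#FFEB3B`, blue cofactors `#A0CED9`, green
22-unit reaction curves `#43A047`).

## Command line

```sh
netglyph render model.txt -o out.svg --template sbgn --seed 7
netglyph render model.xml -o out.png --overlay fluxes.csv --overlay-mode color --colorbar
```

Exit codes: 0 success, 1 validation error, 2 I/O error.

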