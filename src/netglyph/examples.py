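"""Packaged worked example: the TCA-cycle figure.

:func:`tca_pipeline` runs the complete demonstration script — load the
TCA-cycle model, create cofactor aliases, style compartments/species/
reactions, align pyruvate dehydrogenase (J1) vertically above the cycle and
the eight core reactions (J2..J9) on a circle, and set the final canvas.  It
returns the handle; pass ``outdir`` to also write the PDF/SVG/SBML files.
"""

from __future__ import annotations

import os

from .api import NetworkHandle, load
from .model import TCA_MODEL_TEXT

#: alias plan for ubiquitous cofactors, one visual copy per using reaction
TCA_ALIASES = {
    "J2": ["CoA"],
    "J4": ["NAD", "NADH", "CO2"],
    "J5": ["CoA", "NAD", "NADH", "CO2"],
    "J6": ["CoA"],
    "J8": ["H2O"],
    "J9": ["NAD", "NADH"],
}

TCA_CORE_SPECIES = [
    "Pyr", "AcCoA", "Cit", "IsoCit", "aKG", "SCoA", "Succ", "Fum", "Mal", "Oxalo",
]
TCA_SMALL_MOLECULES = ["H2O", "CO2", "Pi"]
TCA_COFACTORS = ["NAD", "NADH", "FAD", "FADH2", "GTP", "CoA", "GDP"]

CIRCLE_CENTER = (2200.0, 2800.0)
CIRCLE_RADIUS = 1500.0
ARC_START, ARC_END = 105.0, -255.0
J1_CENTER, J1_SPREAD = (2200.0, 700.0), 800.0
CANVAS = (4500.0, 5000.0)


def tca_pipeline(seed: int = 0, outdir: str | None = None) -> NetworkHandle:
    """Run the TCA-cycle demonstration end to end."""
    net = load(TCA_MODEL_TEXT, seed=seed)

    net.create_aliases(TCA_ALIASES)

    compartment = net.get_compartment()
    compartment.set_font_color("#8BC34A")
    compartment.set_font_size(200)
    compartment.get_label().align_to_vertical_center()

    species_list = net.get_species_list()
    species_list.set_shapes("circle")
    species_list.set_font_sizes(40)

    core_species = net.get_species_list(TCA_CORE_SPECIES)
    core_species.set_sizes((130, 130))
    core_species.set_fill_colors("#FFEB3B")

    small_molecules = net.get_species_list(TCA_SMALL_MOLECULES)
    small_molecules.set_sizes((90, 90))
    small_molecules.set_fill_colors("#FFEB3B")

    cofactors = net.get_species_list(TCA_COFACTORS)
    cofactors.set_sizes((80, 80))
    cofactors.set_fill_colors("#A0CED9")
    cofactors.set_font_sizes(25)

    reactions = net.get_reactions_list()
    reactions.switch_to_curve()
    reactions.set_thicknesses(22)
    reactions.set_colors("#43A047")

    net.get_reactions_list(["J2", "J3", "J4", "J5", "J6", "J7", "J8", "J9"]).align_circle(
        center_at=CIRCLE_CENTER, radius=CIRCLE_RADIUS, arc_start=ARC_START, arc_end=ARC_END
    )
    net.get_reaction("J1").align_vertical(center_at=J1_CENTER, spread=J1_SPREAD)

    net.set_size(CANVAS)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        net.draw(os.path.join(outdir, "TCA_Cycle.pdf"))
        net.draw(os.path.join(outdir, "TCA_Cycle.svg"))
        net.save(os.path.join(outdir, "TCA_Cycle.xml"))
    return net
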