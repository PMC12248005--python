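"""Style templates, the resolution cascade, batch attribute setting, colors."""

import copy

import pytest

from netglyph import (
    apply_default_template,
    apply_template,
    generate_layout,
    html_color,
    parse_model,
    resolve_style,
    set_group_attribute,
)
from netglyph.errors import StyleError
from netglyph.layout import create_source_sink_glyph
from netglyph.style import CurvePrimitive, Ellipse, RenderGroup, Style


@pytest.fixture()
def small_layout():
    return generate_layout(parse_model("R1: A -> B;"), (400, 400))


def test_every_glyph_resolves(tca_handle):
    lay, render = tca_handle.layout, tca_handle.render
    for g in lay.all_glyphs():
        group = resolve_style(render, g)
        assert group.stroke_width is not None and group.font_size is not None


def test_empty_layout_default_template():
    render = apply_default_template(generate_layout(parse_model(""), (10, 10)))
    assert sum(1 for s in render.styles if s.type_list) == 4
    assert sum(1 for s in render.styles if s.id_list) == 0


def test_product_references_carry_arrowhead(small_layout):
    render = apply_default_template(small_layout)
    rg = small_layout.get_reaction_glyph("R1")
    sub, prod = rg.species_reference_glyphs
    assert resolve_style(render, prod).end_head == "arrow_triangle"
    assert resolve_style(render, sub).end_head == "none"


def test_sbgn_empty_set_symbol(small_layout):
    glyph = create_source_sink_glyph(small_layout, "R1", "substrate")
    render = apply_template(small_layout, "sbgn")
    shapes = resolve_style(render, glyph).shapes
    assert any(isinstance(s, Ellipse) for s in shapes)
    assert any(isinstance(s, CurvePrimitive) for s in shapes)


def test_escher_curves_thicker_than_default(small_layout):
    default = apply_default_template(small_layout)
    escher = apply_template(small_layout, "escher")
    rg = small_layout.get_reaction_glyph("R1")
    assert (
        resolve_style(escher, rg).stroke_width
        > resolve_style(default, rg).stroke_width
    )


def test_template_determinism(small_layout):
    assert apply_template(small_layout, "sbgn") == apply_template(small_layout, "sbgn")


def test_unknown_template_lists_available(small_layout):
    with pytest.raises(StyleError, match="sbgn"):
        apply_template(small_layout, "blorp")


# --- batch setting and the cascade -----------------------------------------


def test_core_species_fill_batch_override(tca_handle):
    from netglyph.examples import TCA_CORE_SPECIES

    lay, render = tca_handle.layout, tca_handle.render
    core_ids = {
        g.id for g in lay.species_glyphs if g.species_id in set(TCA_CORE_SPECIES)
    }
    for gid in core_ids:
        assert resolve_style(render, lay.get_species_glyph(gid)).fill == "#FFEB3B"


def test_cofactor_fill_and_font(tca_handle):
    from netglyph.examples import TCA_COFACTORS

    lay, render = tca_handle.layout, tca_handle.render
    for g in lay.species_glyphs:
        if g.species_id in set(TCA_COFACTORS):
            assert resolve_style(render, g).fill == "#A0CED9"
            (label,) = lay.text_glyphs_of(g.id)
            assert resolve_style(render, label).font_size == 25


def test_reaction_thickness_22(tca_handle):
    lay, render = tca_handle.layout, tca_handle.render
    for rg in lay.reaction_glyphs:
        assert resolve_style(render, rg).stroke_width == 22
        for srg in rg.species_reference_glyphs:
            g = resolve_style(render, srg, parent_reaction_glyph_id=rg.id)
            assert g.stroke_width == 22 and g.stroke == "#43A047"


def test_empty_glyph_set_is_noop(small_layout):
    render = apply_default_template(small_layout)
    before = copy.deepcopy(render)
    set_group_attribute(render, set(), "fill", "#123456")
    assert render == before


def test_unknown_attribute_rejected(small_layout):
    render = apply_default_template(small_layout)
    with pytest.raises(StyleError):
        set_group_attribute(render, {"A_glyph"}, "sparkles", 1)


def test_id_over_role_over_type_precedence(small_layout):
    render = apply_default_template(small_layout)
    rg = small_layout.get_reaction_glyph("R1")
    prod = rg.species_reference_glyphs[1]
    # role tier overrides the type tier...
    render.styles.append(
        Style("role_override", RenderGroup(stroke="#111111"), role_list={"product"})
    )
    assert resolve_style(render, prod).stroke == "#111111"
    # ...and the id tier overrides the role tier
    set_group_attribute(render, {prod.id}, "stroke", "#222222")
    assert resolve_style(render, prod).stroke == "#222222"


def test_later_style_wins_within_tier(small_layout):
    render = apply_default_template(small_layout)
    g = small_layout.get_species_glyph("A_glyph")
    render.styles.append(Style("first", RenderGroup(fill="#AAAAAA"), id_list={g.id}))
    render.styles.append(Style("second", RenderGroup(fill="#BBBBBB"), id_list={g.id}))
    assert resolve_style(render, g).fill == "#BBBBBB"


def test_resolution_is_pure(small_layout):
    render = apply_default_template(small_layout)
    g = small_layout.get_species_glyph("A_glyph")
    assert resolve_style(render, g) == resolve_style(render, g)


def test_overrides_survive_re_resolution(small_layout):
    render = apply_template(small_layout, "escher")
    g = small_layout.get_species_glyph("A_glyph")
    set_group_attribute(render, {g.id}, "fill", "#FFEB3B")
    first = resolve_style(render, g)
    second = resolve_style(render, g)
    assert first.fill == second.fill == "#FFEB3B"
    # untouched attributes still come from the template
    assert first.stroke == "#6A4A8C"


# --- named colors ----------------------------------------------------------


def test_html_colors():
    assert html_color("red") == "#FF0000"
    assert html_color("WHITE") == "#FFFFFF"
    with pytest.raises(StyleError):
        html_color("notacolor")


def test_html_color_suggests_near_misses():
    with pytest.raises(StyleError, match="did you mean"):
        html_color("redd")
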