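"""Fluent handle API, load/save/draw, and the CLI."""

import os

import pytest
from click.testing import CliRunner

import netglyph
from netglyph.cli import main as cli_main
from netglyph.errors import LayoutError, NetglyphError
from netglyph.model import TCA_MODEL_TEXT
from tests.test_sbmlio import quantized


def test_load_model_text_builds_full_scene():
    net = netglyph.load(TCA_MODEL_TEXT)
    assert len(net.layout.reaction_glyphs) == 9
    assert net.render.styles  # complete render data
    # curves are routed
    assert all(
        srg.curve
        for rg in net.layout.reaction_glyphs
        for srg in rg.species_reference_glyphs
    )


def test_load_empty_source():
    net = netglyph.load("")
    assert net.network.species == [] and net.layout.compartment_glyphs


def test_load_garbage_reports_both_parsers():
    with pytest.raises(NetglyphError, match="neither"):
        netglyph.load("!! {giberish} !!")


def test_load_preserves_existing_layout(tmp_path, tca_handle):
    path = tmp_path / "tca.xml"
    tca_handle.save(str(path))
    again = netglyph.load(str(path))
    assert again.layout == quantized(tca_handle.layout)  # positions untouched


def test_save_load_round_trip_state(tmp_path, tca_handle):
    path = tmp_path / "tca.xml"
    tca_handle.save(str(path))
    again = netglyph.load(str(path))
    assert again.network == tca_handle.network
    assert again.render == tca_handle.render


def test_set_sizes_preserves_center(tca_handle):
    g = tca_handle.layout.species_glyphs_of("Pyr")[0]
    center = g.bounding_box.center
    tca_handle.get_species_list(["Pyr"]).set_sizes((130, 130))
    assert g.bounding_box.width == 130 and g.bounding_box.height == 130
    assert g.bounding_box.center == center


def test_unknown_ids_are_named():
    net = netglyph.load("R1: A -> B;")
    with pytest.raises(LayoutError, match="nope"):
        net.get_reaction("nope")
    with pytest.raises(LayoutError, match="ghost"):
        net.get_species_list(["ghost"])


def test_draw_svg_deterministic(tmp_path, tca_handle):
    p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
    tca_handle.draw(str(p1))
    tca_handle.draw(str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_draw_unknown_extension(tca_handle, tmp_path):
    with pytest.raises(LayoutError, match="xyz"):
        tca_handle.draw(str(tmp_path / "out.xyz"))


def test_draw_pdf_nonempty(tmp_path, tca_handle):
    out = tmp_path / "TCA_Cycle.pdf"
    tca_handle.draw(str(out))
    assert out.stat().st_size > 1000


def test_save_unwritable_path(tca_handle):
    with pytest.raises(NetglyphError):
        tca_handle.save("/nonexistent-dir/out.xml")


def test_mutations_append_log_records():
    net = netglyph.load("R1: A -> B;")
    n0 = len(net.log)
    net.get_species_list().set_fill_colors("tomato")  # named colors accepted
    assert len(net.log) > n0


def test_compartment_label_alignment(tca_handle):
    cg = tca_handle.get_compartment().glyph
    (label,) = tca_handle.layout.text_glyphs_of(cg.id)
    tca_handle.get_compartment().get_label().align_to_top()
    assert label.bounding_box.position.y == cg.bounding_box.position.y


# --- CLI -------------------------------------------------------------------


@pytest.fixture()
def model_file(tmp_path):
    p = tmp_path / "model.txt"
    p.write_text("R1: A -> B;\nR2: B -> C;\n")
    return str(p)


def test_cli_render_svg(model_file, tmp_path):
    out = str(tmp_path / "out.svg")
    result = CliRunner().invoke(cli_main, ["render", model_file, "-o", out, "--seed", "3"])
    assert result.exit_code == 0, result.output
    assert os.path.getsize(out) > 0


def test_cli_overlay_with_colorbar(model_file, tmp_path):
    values = tmp_path / "flux.csv"
    values.write_text("id,value\nR1,0.5\nR2,2.5\n")
    out = str(tmp_path / "out.xml")
    result = CliRunner().invoke(
        cli_main,
        ["render", model_file, "-o", out, "--overlay", str(values), "--colorbar"],
    )
    assert result.exit_code == 0, result.output
    _, lay, _ = netglyph.read_sbml(open(out).read())
    assert any(g.id.startswith("colorbar_") for g in lay.graphical_objects)


def test_cli_config_overrides_autolayout(model_file, tmp_path):
    cfg = tmp_path / "layout.cfg"
    cfg.write_text("iterations = 5\nk_scale = 0.5  # tighter packing\n")
    out = str(tmp_path / "out.svg")
    result = CliRunner().invoke(
        cli_main, ["render", model_file, "-o", out, "--config", str(cfg)]
    )
    assert result.exit_code == 0, result.output
    assert os.path.getsize(out) > 0


def test_cli_bad_model_exits_1(tmp_path):
    bad = tmp_path / "bad.txt"
    bad.write_text("not a model !!")
    result = CliRunner().invoke(
        cli_main, ["render", str(bad), "-o", str(tmp_path / "x.svg")]
    )
    assert result.exit_code == 1
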