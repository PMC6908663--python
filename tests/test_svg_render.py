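import xml.etree.ElementTree as ET

import pytest
from oracles import svg_age_scale

from phenontree.datapack_io import parse_datapack
from phenontree.fixtures import FixtureSpec, random_fixture
from phenontree.integration import compute_relationship_map
from phenontree.layout import ChartSettings, position_chart
from phenontree.svg_render import StyleSpec, render, render_component_trees
from phenontree.tree_model import build_trees, resolve_colors

NS = "{http://www.w3.org/2000/svg}"
KNOWN_ELEMENTS = {
    "svg", "g", "line", "rect", "text", "polyline", "polygon", "title", "metadata",
}


def test_svg_well_formed_known_elements(example_svg):
    from lxml import etree

    root = etree.fromstring(example_svg.encode())
    tags = {etree.QName(el).localname for el in root.iter() if isinstance(el.tag, str)}
    assert tags <= KNOWN_ELEMENTS
    assert etree.QName(root).localname == "svg"


def _side_runs_in_ages(svg_text, box_id, side):
    """(style token, old age, young age) for each run on one box side."""
    root, ns, to_age = svg_age_scale(svg_text)
    box = next(g for g in root.iter(f"{ns}g") if g.get("id") == box_id)
    runs = []
    for line in box.iter(f"{ns}line"):
        cls = line.get("class", "")
        if f"side-{side}" not in cls:
            continue
        token = next(c[len("style-"):] for c in cls.split() if c.startswith("style-"))
        y1, y2 = float(line.get("y1")), float(line.get("y2"))
        runs.append((token, to_age(min(y1, y2)), to_age(max(y1, y2))))
    return runs


def test_aa_box_sides_carry_style_runs(example_svg):
    """Aa (13-0 Ma, frequent below 5 Ma, conjectured above): the sides show
    the frequent style for 8 Myr up from the base and the conjectured style
    for 5 Myr down from the top."""
    for side in ("left", "right"):
        runs = {
            token: (young, old)
            for token, young, old in _side_runs_in_ages(example_svg, "box-Aa", side)
        }
        young, old = runs["frequent"]
        assert old == pytest.approx(13.0, abs=1e-6)
        assert old - young == pytest.approx(8.0, abs=1e-6)
        young, old = runs["conjectured"]
        assert young == pytest.approx(0.0, abs=1e-6)
        assert old - young == pytest.approx(5.0, abs=1e-6)


def test_base_and_top_edges_use_adjacent_styles(example_svg):
    root = ET.fromstring(example_svg)
    box = next(g for g in root.iter(f"{NS}g") if g.get("id") == "box-Aa")
    lines = {line.get("class", ""): line for line in box.iter(f"{NS}line")}
    base = next(l for c, l in lines.items() if "side-base" in c)
    top = next(l for c, l in lines.items() if "side-top" in c)
    # frequent is solid 2.0; conjectured dashed 1.0
    assert float(base.get("stroke-width")) == 2.0 and base.get("stroke-dasharray") is None
    assert top.get("stroke-dasharray") is not None


def test_box_fill_uses_inherited_color_at_alpha(example_svg, example_layout):
    root = ET.fromstring(example_svg)
    box = next(g for g in root.iter(f"{NS}g") if g.get("id") == "box-Aa")
    rect = box.find(f"{NS}rect")
    assert rect.get("fill") == "#008000"  # green, inherited from the branch
    assert float(rect.get("fill-opacity")) == pytest.approx(
        example_layout.settings.box_alpha
    )
    assert 0.0 < float(rect.get("fill-opacity")) < 1.0


def test_species_borders_thicker_than_phenon_lines(example_svg):
    """The species default style renders strictly thicker than the phenon
    default, so boxes stand out from the lines inside them."""
    root = ET.fromstring(example_svg)
    side_widths = set()
    run_widths = set()
    for line in root.iter(f"{NS}line"):
        cls = line.get("class", "")
        if "box-side" in cls and "style-frequent" in cls:
            side_widths.add(float(line.get("stroke-width")))
        if "segment-run" in cls and "style-frequent" not in cls:
            run_widths.add(float(line.get("stroke-width")))
    assert side_widths and min(side_widths) > 0
    spec = StyleSpec()
    assert spec.tokens["frequent"][0] > spec.tokens["common"][0]


def test_segment_y_extents_invert_to_ages(example_svg, example_map):
    root, ns, to_age = svg_age_scale(example_svg)
    for species in example_map.species_order:
        for seg in example_map.group(species):
            gid = f"seg-{seg.phenon_name}-{species}"
            g = next(g for g in root.iter(f"{ns}g") if g.get("id") == gid)
            ys = []
            for line in g.iter(f"{ns}line"):
                if "segment-run" in line.get("class", ""):
                    ys += [float(line.get("y1")), float(line.get("y2"))]
            assert to_age(max(ys)) == pytest.approx(seg.old_age, abs=1e-6)
            assert to_age(min(ys)) == pytest.approx(seg.young_age, abs=1e-6)


def test_guide_symbols_anchor_at_segment_endpoints(example_svg, example_map):
    """Phenon b: chevrons of the break sit at the cut age in both boxes."""
    root, ns, to_age = svg_age_scale(example_svg)
    anchors = {}
    for g in root.iter(f"{ns}g"):
        gid = g.get("id", "")
        if not gid.startswith("seg-b-"):
            continue
        for el in list(g):
            cls = el.get("class", "")
            if "symbol-broken_top" in cls or "symbol-broken_base" in cls:
                pts = el.get("points").split()
                mid_y = float(pts[1].split(",")[1])
                anchors[(gid, cls.split()[-1])] = to_age(mid_y)
    assert anchors[("seg-b-Aa", "symbol-broken_top")] == pytest.approx(10.0, abs=1e-6)
    assert anchors[("seg-b-Bb", "symbol-broken_base")] == pytest.approx(10.0, abs=1e-6)


def test_popup_text_embedded_as_titles():
    text = (
        "\tonly\t10\tfrequent\tthe species popup\n\tonly\t2\tTOP\n"
        "\tx\t8\tfrequent\tthe phenon popup\n\tx\t3\tTOP\t\t\tphenon\tonly\n"
    )
    species, phena = build_trees(parse_datapack(text))
    rmap = compute_relationship_map(species, phena)
    layout = position_chart(species, phena, rmap)
    svg = render(layout, rmap)
    root = ET.fromstring(svg)
    titles = {t.text for t in root.iter(f"{NS}title")}
    assert {"the species popup", "the phenon popup"} <= titles


def test_empty_chart_is_valid_svg_with_axis():
    species, phena = build_trees(parse_datapack(""))
    rmap = compute_relationship_map(species, phena)
    layout = position_chart(species, phena, rmap)
    root = ET.fromstring(render(layout, rmap))
    assert root.find(f"{NS}g[@class='age-axis']") is not None
    assert root.find(f"{NS}g[@class='species-boxes']") is not None


def test_background_bands_behind_everything():
    settings = ChartSettings(background_bands=((10.0, 5.0, "#fde", "interval"),))
    species, phena = build_trees(
        parse_datapack("\tonly\t10\tfrequent\n\tonly\t2\tTOP\n")
    )
    rmap = compute_relationship_map(species, phena)
    layout = position_chart(species, phena, rmap, settings)
    root = ET.fromstring(render(layout, rmap))
    children = [c for c in list(root) if c.tag != f"{NS}metadata"]
    assert children[0].get("class") == "background-bands"


def test_component_tree_species_counts(example_trees):
    """The plain species tree: 5 vertical ranges, 4 horizontal branches."""
    species, _ = example_trees
    root = ET.fromstring(render_component_trees(species))
    ranges = [g for g in root.iter(f"{NS}g") if g.get("class") == "range"]
    branches = [l for l in root.iter(f"{NS}line") if l.get("class") == "branch"]
    assert len(ranges) == 5 and len(branches) == 4


def test_component_tree_single_range():
    species, _ = build_trees(parse_datapack("\tonly\t10\tfrequent\n\tonly\t2\tTOP\n"))
    root = ET.fromstring(render_component_trees(species))
    ranges = [g for g in root.iter(f"{NS}g") if g.get("class") == "range"]
    assert len(ranges) == 1


def test_component_tree_element_count_audit():
    """Element counts are exact: one range group per taxon, one branch line
    per visible branch, one label per taxon."""
    pack = random_fixture(FixtureSpec(seed=7, n_species=30, n_phena=0))
    species, _ = build_trees(pack)
    resolve_colors(species)
    root = ET.fromstring(render_component_trees(species))
    ranges = [g for g in root.iter(f"{NS}g") if g.get("class") == "range"]
    branches = [l for l in root.iter(f"{NS}line") if l.get("class") == "branch"]
    labels = [t for t in root.iter(f"{NS}text") if t.get("class") == "range-label"]
    assert len(ranges) == len(species.ranges)
    assert len(branches) == sum(1 for b in species.branches if b.visible)
    assert len(labels) == len(species.ranges)
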