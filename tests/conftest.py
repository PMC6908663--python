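import pytest

from phenontree import (
    build_trees,
    compute_relationship_map,
    worked_example_fixture,
    parse_datapack,
    position_chart,
    render,
    resolve_colors,
    write_datapack,
)


@pytest.fixture(scope="session")
def example_pack():
    return worked_example_fixture("I")


@pytest.fixture(scope="session")
def example_trees(example_pack):
    species, phena = build_trees(example_pack)
    resolve_colors(species)
    resolve_colors(phena)
    return species, phena


@pytest.fixture(scope="session")
def example_map(example_trees):
    species, phena = example_trees
    return compute_relationship_map(species, phena)


@pytest.fixture(scope="session")
def example_layout(example_trees, example_map):
    species, phena = example_trees
    return position_chart(species, phena, example_map)


@pytest.fixture(scope="session")
def example_svg(example_layout, example_map):
    return render(example_layout, example_map)


@pytest.fixture(scope="session")
def example_roundtrip(example_pack):
    return parse_datapack(write_datapack(example_pack))
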