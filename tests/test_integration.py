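import pytest
from oracles import oracle_box_components, oracle_chain, oracle_split, raw_tables

from phenontree.datapack_io import parse_datapack
from phenontree.fixtures import FixtureSpec, random_fixture
from phenontree.integration import (
    BaseSymbol,
    IntegrationError,
    OrderMode,
    PhenonSegment,
    SegmentSubtree,
    TopSymbol,
    ancestral_chain,
    compute_relationship_map,
    map_to_table,
    order_group,
    split_phenon,
    subtrees_in_box,
)
from phenontree.tree_model import build_trees

TOL = 1e-9


def _chain_pack(depth: int) -> str:
    """A linear species chain s1 -> s2 -> ... with strictly older bases."""
    lines = []
    for i in range(depth):
        base, top = 10 * (depth - i), 0
        lines.append(f"\ts{i + 1}\t{base}\tfrequent")
        lines.append(f"\ts{i + 1}\t{top}\tTOP")
    for i in range(1, depth):
        lines.append(f"\ts{i}\t{10 * (depth - i)}\tbranch\ts{i + 1}")
    return "\n".join(lines) + "\n"


def test_ancestral_chain_example(example_trees):
    species, _ = example_trees
    assert ancestral_chain(species, "Be") == ["Be", "Bb", "Aa", "ancestor"]
    assert ancestral_chain(species, "ancestor") == ["ancestor"]


def test_ancestral_chain_deep_path_matches_brute_force():
    pack = parse_datapack(_chain_pack(10))
    species, _ = build_trees(pack)
    chain = ancestral_chain(species, "s10")
    sp, _, _, parent_of, _ = raw_tables(pack)
    assert chain == oracle_chain("s10", parent_of)
    assert len(chain) == 10
    bases = [species.ranges[n].base_age for n in chain]
    assert bases == sorted(bases)  # strictly increasing rootward
    assert len(set(bases)) == len(bases)


def test_ancestral_chain_unknown_species(example_trees):
    species, _ = example_trees
    with pytest.raises(IntegrationError):
        ancestral_chain(species, "nobody")


def test_split_phenon_b_breaks_at_species_origin(example_trees):
    """Phenon b (12-8 Ma, ending in Bb whose FAD is 10 Ma) breaks into two
    parts: the older in the ancestor box Aa, the younger in Bb."""
    species, phena = example_trees
    segs = split_phenon(phena.ranges["b"], species)
    assert [(s.host_species, s.old_age, s.young_age) for s in segs] == [
        ("Aa", 12.0, 10.0),
        ("Bb", 10.0, 8.0),
    ]
    assert segs[0].base_symbol is BaseSymbol.RANGE_ORIGIN
    assert segs[0].top_symbol is TopSymbol.BROKEN_TOP
    assert segs[1].base_symbol is BaseSymbol.BROKEN_BASE
    assert segs[1].top_symbol is TopSymbol.RANGE_TOP_EXTINCT


def test_split_phenon_wholly_inside_one_box(example_trees):
    species, phena = example_trees
    (seg,) = split_phenon(phena.ranges["e"], species)
    assert seg.host_species == "Be"
    assert seg.base_symbol is BaseSymbol.RANGE_ORIGIN
    assert seg.top_symbol is TopSymbol.RANGE_TOP_LIVING  # e reaches the present


def test_split_phenon_three_box_chain():
    """A phenon spanning both intermediate FADs of a three-species chain
    yields three parts whose union is the original interval."""
    text = _chain_pack(3) + "\tq\t25\tfrequent\n\tq\t1\tTOP\t\t\tphenon\ts3\n"
    species, phena = build_trees(parse_datapack(text))
    segs = split_phenon(phena.ranges["q"], species)
    sp, ph, terminal, parent_of, _ = raw_tables(parse_datapack(text))
    assert [(s.host_species, s.old_age, s.young_age) for s in segs] == oracle_split(
        25.0, 1.0, "s3", sp, parent_of
    )
    assert len(segs) == 3
    assert segs[0].old_age == 25.0 and segs[-1].young_age == 1.0
    for a, b in zip(segs, segs[1:]):
        assert a.young_age == b.old_age


def test_split_tie_at_speciation_keeps_origin_in_that_box(example_trees):
    """A phenon whose FAD coincides with a species FAD originates in that
    species' box — no zero-length part in the ancestor."""
    text = (
        "\tp\t10\tfrequent\n\tp\t0\tTOP\n\tc\t6\tfrequent\n\tc\t2\tTOP\n"
        "\tp\t6\tbranch\tc\n"
        "\tx\t6\tfrequent\n\tx\t3\tTOP\t\t\tphenon\tc\n"
    )
    species, phena = build_trees(parse_datapack(text))
    (seg,) = split_phenon(phena.ranges["x"], species)
    assert seg.host_species == "c" and seg.base_symbol is BaseSymbol.RANGE_ORIGIN


def test_split_errors():
    base = (
        "\tp\t10\tfrequent\n\tp\t4\tTOP\n\tc\t6\tfrequent\n\tc\t2\tTOP\n"
        "\tp\t6\tbranch\tc\n"
    )
    # phenon TOP at the species FAD boundary: ends outside its species
    text = base + "\tx\t8\tfrequent\n\tx\t6\tTOP\t\t\tphenon\tc\n"
    species, phena = build_trees(parse_datapack(text))
    with pytest.raises(IntegrationError, match="outside its species"):
        split_phenon(phena.ranges["x"], species)
    # phenon outliving its host species
    text = base + "\tx\t8\tfrequent\n\tx\t1\tTOP\t\t\tphenon\tc\n"
    species, phena = build_trees(parse_datapack(text))
    with pytest.raises(IntegrationError, match="outside its species"):
        split_phenon(phena.ranges["x"], species)
    # phenon predating the root species FAD
    text = base + "\tx\t12\tfrequent\n\tx\t3\tTOP\t\t\tphenon\tc\n"
    species, phena = build_trees(parse_datapack(text))
    with pytest.raises(IntegrationError, match="predates root"):
        split_phenon(phena.ranges["x"], species)


def test_relationship_map_reproduces_published_groups(example_map):
    rmap = example_map
    assert rmap.species_order == ["ancestor", "Aa", "Bb", "Be", "Bf"]
    members = {sp: [s.phenon_name for s in rmap.group(sp)] for sp in rmap.species_order}
    assert members == {
        "ancestor": ["phenon"],
        "Aa": ["a", "b"],
        "Bb": ["b", "c", "d", "f"],
        "Be": ["c", "d", "e"],
        "Bf": ["f"],
    }
    assert [e[0] for e in rmap.entries] == [
        "1-1", "2-1", "2-2", "3-1", "3-2", "3-3", "3-4", "4-1", "4-2", "4-3", "5-1",
    ]


def test_relationship_map_single_species_single_phenon():
    text = (
        "\tonly\t10\tfrequent\n\tonly\t0\tTOP\n"
        "\tx\t8\tfrequent\n\tx\t2\tTOP\t\t\tphenon\tonly\n"
    )
    species, phena = build_trees(parse_datapack(text))
    rmap = compute_relationship_map(species, phena)
    assert rmap.entries == [("1-1", "only", "x")]


def test_species_without_phena_get_empty_groups(example_trees):
    species, phena = example_trees
    import copy

    ph = copy.deepcopy(phena)
    ph.ranges.pop("f")
    ph.branches = [b for b in ph.branches if b.child != "f"]
    rmap = compute_relationship_map(species, ph)
    assert rmap.group_size("Bf") == 0 and "Bf" in rmap.groups


@pytest.mark.parametrize("seed", range(40))
def test_split_matches_interval_oracle(seed):
    pack = random_fixture(
        FixtureSpec(seed=seed, n_species=4 + seed % 8, n_phena=12, crossing_probability=0.7)
    )
    species, phena = build_trees(pack)
    sp, ph, terminal, parent_of, _ = raw_tables(pack)
    for name, (base, top) in ph.items():
        segs = split_phenon(phena.ranges[name], species)
        expect = oracle_split(base, top, terminal[name], sp, parent_of)
        got = [(s.host_species, s.old_age, s.young_age) for s in segs]
        assert len(got) == len(expect)
        for (gh, go, gy), (eh, eo, ey) in zip(got, expect):
            assert gh == eh and abs(go - eo) <= TOL and abs(gy - ey) <= TOL


def test_segment_count_formula(example_trees):
    """Part count = chain FADs strictly inside the phenon's open interval + 1."""
    species, phena = example_trees
    for name, rng in phena.ranges.items():
        chain = ancestral_chain(species, rng.terminal_species)
        inside = sum(
            1
            for s in chain
            if rng.top_age + TOL < species.ranges[s].base_age < rng.base_age - TOL
        )
        assert len(split_phenon(rng, species)) == inside + 1


def test_be_contains_two_disconnected_subtrees(example_map, example_trees):
    _, phena = example_trees
    trees = example_map.subtrees["Be"]
    flat = [[s.phenon_name for s in t.flatten()] for t in trees]
    assert flat == [["c"], ["d", "e"]]


def test_single_unsplit_phenon_is_singleton_subtree():
    text = (
        "\tonly\t10\tfrequent\n\tonly\t0\tTOP\n"
        "\tx\t8\tfrequent\n\tx\t2\tTOP\t\t\tphenon\tonly\n"
    )
    species, phena = build_trees(parse_datapack(text))
    rmap = compute_relationship_map(species, phena)
    assert len(rmap.subtrees["only"]) == 1
    assert not rmap.subtrees["only"][0].children


@pytest.mark.parametrize("seed", range(25))
def test_box_subtrees_match_component_oracle(seed):
    pack = random_fixture(FixtureSpec(seed=seed + 500, n_species=6, n_phena=20))
    species, phena = build_trees(pack)
    rmap = compute_relationship_map(species, phena)
    _, _, _, _, ph_branches = raw_tables(pack)
    for sp_name in rmap.species_order:
        group = rmap.group(sp_name)
        box_segments = {s.phenon_name: (s.old_age, s.young_age) for s in group}
        expect = set(
            oracle_box_components(list(box_segments), box_segments, ph_branches)
        )
        got = {
            frozenset(s.phenon_name for s in t.flatten()) for t in rmap.subtrees[sp_name]
        }
        assert got == expect


def _seg(name, old, young):
    return SegmentSubtree(
        root=PhenonSegment(
            name, "sp", old, young, TopSymbol.RANGE_TOP_EXTINCT, BaseSymbol.RANGE_ORIGIN
        )
    )


def test_order_group_modes():
    trees = [_seg("f", 7, 1), _seg("c", 9, 3), _seg("d", 8, 0)]
    assert [t.root.phenon_name for t in order_group(trees)] == ["c", "d", "f"]
    assert [
        t.root.phenon_name for t in order_group(trees, OrderMode.LAST_OCCURRENCE)
    ] == ["d", "f", "c"]
    assert [
        t.root.phenon_name for t in order_group(trees, OrderMode.ALPHABETIC)
    ] == ["c", "d", "f"]


def test_order_group_is_stable_on_ties():
    trees = [_seg("z", 8, 1), _seg("a", 8, 1)]
    assert [t.root.phenon_name for t in order_group(trees)] == ["z", "a"]


def test_map_table_export(example_map):
    table = map_to_table(example_map)
    lines = table.strip().splitlines()
    assert lines[0].startswith("relationship_id\t")
    assert "3-2\tBb\t4\tc\tBb <- c" in lines
    assert "4-3\tBe\t3\te\tBe <- e" in lines
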