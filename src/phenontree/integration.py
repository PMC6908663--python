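"""The species-phenon integration algorithm.

A phenon's range ends inside one species box (its terminal species).  The
earlier part of the range may predate that species: walking the ancestral
chain of species rootward, the range is cut at every species origin (FAD /
branch-connection age) that falls strictly inside it, and the part older
than the cut is transferred to the ancestral species box.  Each resulting
:class:`PhenonSegment` duplicates the phenon's graphical features and is
annotated with guide symbols at both extremities so the viewer can tell a
true range origin / extinction / still-living top from an artificial break
where the range transfers between boxes.

Grouping all segments by host species yields the one-to-many species-phenon
relationship map, the structure from which species-box widths are later
computed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .datapack_io import split_display_label
from .tree_model import AGE_TOL, EvoTree, TaxonRange, style_segments

__all__ = [
    "TopSymbol",
    "BaseSymbol",
    "OrderMode",
    "PhenonSegment",
    "SegmentSubtree",
    "RelationshipMap",
    "IntegrationError",
    "ancestral_chain",
    "split_phenon",
    "compute_relationship_map",
    "subtrees_in_box",
    "order_group",
    "map_to_table",
]


class TopSymbol(enum.Enum):
    RANGE_TOP_EXTINCT = "extinct"
    RANGE_TOP_LIVING = "living"
    BROKEN_TOP = "broken_top"


class BaseSymbol(enum.Enum):
    RANGE_ORIGIN = "origin"
    BROKEN_BASE = "broken_base"


class OrderMode(enum.Enum):
    FIRST_OCCURRENCE = "first"
    LAST_OCCURRENCE = "last"
    ALPHABETIC = "alpha"


class IntegrationError(ValueError):
    pass


@dataclass
class PhenonSegment:
    """One broken-up part of a phenon range, hosted by one species box."""

    phenon_name: str
    host_species: str
    old_age: float
    young_age: float
    top_symbol: TopSymbol
    base_symbol: BaseSymbol
    color: str | None = None
    style_runs: list[tuple[float, float, str]] = field(default_factory=list)
    popup: str = ""
    image: str | None = None

    @property
    def display_label(self) -> str:
        return split_display_label(self.phenon_name)[0]

    @property
    def is_broken_top(self) -> bool:
        return self.top_symbol is TopSymbol.BROKEN_TOP

    @property
    def is_broken_base(self) -> bool:
        return self.base_symbol is BaseSymbol.BROKEN_BASE


@dataclass
class SegmentSubtree:
    """A connected component of phenon segments inside one species box."""

    root: PhenonSegment
    children: list["SegmentSubtree"] = field(default_factory=list)

    def flatten(self) -> list[PhenonSegment]:
        out = [self.root]
        for child in self.children:
            out.extend(child.flatten())
        return out


@dataclass
class RelationshipMap:
    """The one-to-many species -> phenon-segment map.

    ``entries`` are ``(relationship_id, species, phenon)`` triples with ids
    ``"<speciesIndex>-<memberIndex>"`` (1-based): species indexed in
    pre-order traversal of the species tree with roots in first-occurrence
    order, members in the within-box ordering.
    """

    species_order: list[str] = field(default_factory=list)
    groups: dict[str, list[PhenonSegment]] = field(default_factory=dict)
    subtrees: dict[str, list[SegmentSubtree]] = field(default_factory=dict)
    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def group(self, species: str) -> list[PhenonSegment]:
        return self.groups.get(species, [])

    def group_size(self, species: str) -> int:
        return len(self.group(species))

    def segments_of(self, phenon: str) -> list[PhenonSegment]:
        out = [s for g in self.groups.values() for s in g if s.phenon_name == phenon]
        return sorted(out, key=lambda s: -s.old_age)


def ancestral_chain(species_tree: EvoTree, species: str) -> list[str]:
    """``[species, parent, grandparent, ...]`` up to the root of its
    component."""
    if species not in species_tree.ranges:
        raise IntegrationError(f"unknown species {species!r}")
    parent_of = species_tree.parent_of
    chain = [species]
    while chain[-1] in parent_of:
        chain.append(parent_of[chain[-1]])
    return chain


def _cut_runs(
    runs: list[tuple[float, float, str]], old: float, young: float
) -> list[tuple[float, float, str]]:
    """Intersect styled intervals with [young, old]."""
    out = []
    for r_old, r_young, token in runs:
        lo, hi = max(r_young, young), min(r_old, old)
        if hi - lo > AGE_TOL:
            out.append((hi, lo, token))
    return out


def split_phenon(phenon: TaxonRange, species_tree: EvoTree) -> list[PhenonSegment]:
    """Break a phenon range at species origins along its ancestral chain.

    Starting inside the terminal species (where the range's TOP sits), walk
    the chain rootward; whenever the current species' FAD is younger than
    the phenon's remaining extent, cut there: the younger part stays in the
    current box (BROKEN_BASE at the cut), the rest transfers to the parent
    box (BROKEN_TOP at the same age).  The final part carries RANGE_ORIGIN;
    the youngest part carries the living/extinct top symbol.  If the phenon
    origin coincides with a species FAD (within tolerance) no zero-length
    part is emitted — the origin sits at that box's base.

    Returns segments ordered old -> young.  Style runs of the phenon are
    re-cut at the same ages.
    """
    if phenon.terminal_species is None:
        raise IntegrationError(f"range {phenon.name!r} has no terminal species")
    if phenon.terminal_species not in species_tree.ranges:
        raise IntegrationError(
            f"phenon {phenon.name!r}: unknown terminal species {phenon.terminal_species!r}"
        )
    chain = ancestral_chain(species_tree, phenon.terminal_species)
    terminal = species_tree.ranges[chain[0]]
    if phenon.top_age < terminal.top_age - AGE_TOL or phenon.top_age >= terminal.base_age - AGE_TOL:
        raise IntegrationError(
            f"phenon {phenon.name!r} ends outside its species: TOP {phenon.top_age} Ma "
            f"not inside {terminal.name!r} [{terminal.top_age}, {terminal.base_age})"
        )
    runs = style_segments(phenon)
    segments: list[PhenonSegment] = []  # young -> old during the walk
    cur_top = phenon.top_age
    cur_top_symbol = (
        TopSymbol.RANGE_TOP_LIVING if phenon.still_living else TopSymbol.RANGE_TOP_EXTINCT
    )
    placed = False
    for sp_name in chain:
        sp = species_tree.ranges[sp_name]
        if sp.base_age <= cur_top + AGE_TOL and placed:
            # chain species passed through instantaneously (branch at the
            # parent's own FAD) — no zero-length part
            continue
        if phenon.base_age > sp.base_age + AGE_TOL:
            segments.append(
                PhenonSegment(
                    phenon_name=phenon.name,
                    host_species=sp_name,
                    old_age=sp.base_age,
                    young_age=cur_top,
                    top_symbol=cur_top_symbol,
                    base_symbol=BaseSymbol.BROKEN_BASE,
                    color=phenon.color,
                    style_runs=_cut_runs(runs, sp.base_age, cur_top),
                    popup=phenon.popup,
                    image=phenon.image,
                )
            )
            cur_top = sp.base_age
            cur_top_symbol = TopSymbol.BROKEN_TOP
            placed = True
        else:
            segments.append(
                PhenonSegment(
                    phenon_name=phenon.name,
                    host_species=sp_name,
                    old_age=phenon.base_age,
                    young_age=cur_top,
                    top_symbol=cur_top_symbol,
                    base_symbol=BaseSymbol.RANGE_ORIGIN,
                    color=phenon.color,
                    style_runs=_cut_runs(runs, phenon.base_age, cur_top),
                    popup=phenon.popup,
                    image=phenon.image,
                )
            )
            placed = True
            break
    else:
        raise IntegrationError(
            f"phenon {phenon.name!r} predates root species: BASE {phenon.base_age} Ma "
            f"older than FAD {species_tree.ranges[chain[-1]].base_age} Ma of {chain[-1]!r}"
        )
    return list(reversed(segments))


def subtrees_in_box(
    rmap_or_group: "RelationshipMap | list[PhenonSegment]",
    phenon_tree: EvoTree,
    species: str | None = None,
) -> list[SegmentSubtree]:
    """Partition the segments inside one species box into connected subtrees.

    Two segments are connected only where the phenon tree has a branch
    between their phena whose branch-point age lies inside the box's time
    extent — i.e. inside both segments' intervals here — and both are hosted
    by this species.  Every other segment roots its own (possibly singleton)
    subtree.  Roots keep the order in which their segments were grouped;
    children keep the phenon tree's branch authoring (left-right) order.
    """
    if isinstance(rmap_or_group, RelationshipMap):
        group = rmap_or_group.group(species)
    else:
        group = rmap_or_group
    by_phenon = {seg.phenon_name: seg for seg in group}
    nodes = {name: SegmentSubtree(root=seg) for name, seg in by_phenon.items()}
    has_parent: set[str] = set()
    for b in phenon_tree.branches:
        p, c = by_phenon.get(b.parent), by_phenon.get(b.child)
        if p is None or c is None or c.phenon_name in has_parent:
            continue
        if (
            p.young_age - AGE_TOL <= b.age <= p.old_age + AGE_TOL
            and c.young_age - AGE_TOL <= b.age <= c.old_age + AGE_TOL
        ):
            nodes[b.parent].children.append(nodes[b.child])
            has_parent.add(b.child)
    return [nodes[seg.phenon_name] for seg in group if seg.phenon_name not in has_parent]


def order_group(
    subtrees: list[SegmentSubtree], mode: OrderMode = OrderMode.FIRST_OCCURRENCE
) -> list[SegmentSubtree]:
    """Stable sort of root subtrees: First Occurrence (oldest base first,
    the default), Last Occurrence (youngest top first), or Alphabetic
    (case-insensitive display label).  Connected subtrees keep their
    internal phenon-tree left-right structure."""
    if mode is OrderMode.FIRST_OCCURRENCE:
        return sorted(subtrees, key=lambda t: -t.root.old_age)
    if mode is OrderMode.LAST_OCCURRENCE:
        return sorted(subtrees, key=lambda t: t.root.young_age)
    return sorted(subtrees, key=lambda t: t.root.display_label.casefold())


def _species_index_order(species_tree: EvoTree) -> list[str]:
    roots = sorted(
        species_tree.roots, key=lambda n: -species_tree.ranges[n].base_age
    )
    return species_tree.preorder(roots)


def compute_relationship_map(
    species_tree: EvoTree,
    phenon_tree: EvoTree,
    mode: OrderMode = OrderMode.FIRST_OCCURRENCE,
) -> RelationshipMap:
    """Split every phenon and group the segments by host species.

    Species are indexed by a deterministic pre-order traversal of the
    species tree (roots in first-occurrence order); members within a box
    follow :func:`order_group`.  Species without phena get an empty group.
    Errors from individual phena are aggregated with their names.
    """
    rmap = RelationshipMap(species_order=_species_index_order(species_tree))
    rmap.groups = {name: [] for name in rmap.species_order}
    errors: list[str] = []
    for phenon in phenon_tree.ranges.values():
        try:
            for seg in split_phenon(phenon, species_tree):
                rmap.groups.setdefault(seg.host_species, []).append(seg)
        except IntegrationError as err:
            errors.append(str(err))
    if errors:
        raise IntegrationError("; ".join(errors))
    for si, species in enumerate(rmap.species_order, start=1):
        trees = order_group(
            subtrees_in_box(rmap.groups[species], phenon_tree), mode
        )
        rmap.subtrees[species] = trees
        ordered = [seg for tree in trees for seg in tree.flatten()]
        rmap.groups[species] = ordered
        for mi, seg in enumerate(ordered, start=1):
            rmap.entries.append((f"{si}-{mi}", species, seg.phenon_name))
    return rmap


def map_to_table(rmap: RelationshipMap) -> str:
    """Tab-delimited export of the relationship map.

    Columns: relationship id, species, group size, phenon, "species <- phenon".
    Ids are strictly sequential within each species group.
    """
    lines = ["relationship_id\tspecies\tgroup_size\tphenon\trelationship"]
    sizes = {sp: len(g) for sp, g in rmap.groups.items()}
    for rid, species, phenon in rmap.entries:
        lines.append(
            f"{rid}\t{species}\t{sizes[species]}\t{phenon}\t{species} <- {phenon}"
        )
    return "\n".join(lines) + "\n"
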