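"""Collision-free positions and widths for the integrated chart.

Vertical placement is a linear map from age (Ma) to canvas y, younger at
the top, age increasing downward; horizontal placement is computed by a
recursive width pass over the species tree.  A species box must be wide
enough for its ordered group of phenon slots; a subtree must be wide enough
for the parent box plus all child subtrees, which are laid out to the right
of the parent box in branch authoring order.  Because a parent lineage
normally persists alongside its descendants, parent and child boxes overlap
in time and therefore may never share horizontal space — the width
recursion sums rather than maximizes, which guarantees a collision-free
chart for every valid tree.

All geometry is in abstract canvas units (1 unit = 1 px at SVG scale 1);
x grows rightward, y grows downward with age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .integration import OrderMode, PhenonSegment, RelationshipMap, SegmentSubtree
from .tree_model import EvoTree, style_segments

__all__ = [
    "ChartSettings",
    "AgeScale",
    "LayoutBox",
    "Layout",
    "box_inner_width",
    "slot_width",
    "subtree_width",
    "position_chart",
    "position_component_tree",
    "load_settings",
]


@dataclass(frozen=True)
class ChartSettings:
    """Tunable chart parameters.

    Lengths are canvas units; ages Ma.  ``units_per_myr`` is the vertical
    scale.  ``box_alpha`` is the species-box fill opacity, strictly between
    0 and 1 so phenon lines and labels stay legible through the fill.
    ``window`` is the plotted (old, young) age interval; ``None`` defaults
    to [max base age rounded up to a whole Myr, 0].
    """

    units_per_myr: float = 20.0
    font_size_species: float = 12.0
    font_size_phenon: float = 10.0
    label_char_factor: float = 0.6  # label width estimate: chars * font size * factor
    box_alpha: float = 0.25
    min_box_width: float = 40.0
    min_slot_width: float = 16.0
    slot_gap: float = 10.0  # between phenon slots in a box
    sibling_gap: float = 24.0  # between sibling subtrees
    box_padding: float = 8.0
    ordering: OrderMode = OrderMode.FIRST_OCCURRENCE
    default_species_style: str = "frequent"
    default_phenon_style: str = "common"
    default_color: str = "#000000"
    accent_color: str = "#cc0000"  # guide symbols
    show_images: bool = False
    image_width: float = 24.0
    show_labels: bool = True
    window: tuple[float, float] | None = None  # (old, young) Ma
    margin: float = 30.0
    axis_width: float = 46.0
    tick_interval: float = 1.0  # Myr between age-axis ticks
    background_bands: tuple[tuple[float, float, str, str], ...] = ()
    # (old age, young age, colour, label)

    def __post_init__(self) -> None:
        if not (0.0 < self.box_alpha < 1.0):
            raise ValueError("box_alpha must be strictly between 0 and 1")
        for name in (
            "units_per_myr",
            "font_size_species",
            "font_size_phenon",
            "label_char_factor",
            "min_box_width",
            "min_slot_width",
            "tick_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("slot_gap", "sibling_gap", "box_padding", "margin", "axis_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AgeScale:
    """Linear age (Ma) <-> canvas y map; the young window edge is at y_top."""

    old: float
    young: float
    units_per_myr: float
    y_top: float

    def y(self, age: float) -> float:
        return self.y_top + (age - self.young) * self.units_per_myr

    def age(self, y: float) -> float:
        return self.young + (y - self.y_top) / self.units_per_myr

    @property
    def y_bottom(self) -> float:
        return self.y(self.old)


@dataclass
class LayoutBox:
    """A positioned species box."""

    species: str
    x_left: float
    x_right: float
    y_top: float
    y_bottom: float
    top_age: float
    base_age: float
    style_runs: list[tuple[float, float, str]] = field(default_factory=list)
    color: str | None = None
    popup: str = ""
    still_living: bool = False

    @property
    def width(self) -> float:
        return self.x_right - self.x_left

    @property
    def x_center(self) -> float:
        return (self.x_left + self.x_right) / 2.0


@dataclass
class Layout:
    """Positioned chart: boxes, per-segment x positions, branch lines."""

    scale: AgeScale
    settings: ChartSettings
    boxes: dict[str, LayoutBox] = field(default_factory=dict)
    #: (phenon name, host species) -> x of the vertical segment line
    segment_x: dict[tuple[str, str], float] = field(default_factory=dict)
    #: species branches: (parent, child, age, x_from, x_to, color, style, visible)
    species_branches: list[tuple] = field(default_factory=list)
    #: in-box phenon branches: (parent phenon, child phenon, host, age, x_from, x_to, color, style, visible)
    phenon_branches: list[tuple] = field(default_factory=list)
    width: float = 0.0
    height: float = 0.0


def slot_width(segment: PhenonSegment, settings: ChartSettings) -> float:
    """Horizontal room one phenon slot needs: the larger of its display
    label estimate, its thumbnail (when images are shown) and the minimum
    slot width."""
    label_w = len(segment.display_label) * settings.font_size_phenon * settings.label_char_factor
    w = max(label_w if settings.show_labels else 0.0, settings.min_slot_width)
    if settings.show_images and segment.image:
        w = max(w, settings.image_width)
    return w


def box_inner_width(group: list[PhenonSegment], settings: ChartSettings) -> float:
    """Width of a species box from its ordered phenon group: slot widths
    plus inter-slot gaps plus padding both sides; an empty group gets the
    minimum box width."""
    if not group:
        return settings.min_box_width
    total = sum(slot_width(seg, settings) for seg in group)
    total += settings.slot_gap * (len(group) - 1) + 2 * settings.box_padding
    return max(total, settings.min_box_width)


def subtree_width(
    species: str,
    species_tree: EvoTree,
    rmap: RelationshipMap,
    settings: ChartSettings,
    _memo: dict[str, float] | None = None,
) -> float:
    """Recursive width of the subtree rooted at ``species``: its own box
    plus all child subtrees (laid to its right) plus sibling gaps."""
    memo = {} if _memo is None else _memo
    if species in memo:
        return memo[species]
    own = box_inner_width(rmap.group(species), settings)
    total = own
    for child in species_tree.children_of(species):
        total += settings.sibling_gap + subtree_width(child, species_tree, rmap, settings, memo)
    memo[species] = total
    return total


def _default_window(species_tree: EvoTree, phenon_tree: EvoTree) -> tuple[float, float]:
    bases = [r.base_age for t in (species_tree, phenon_tree) for r in t.ranges.values()]
    old = math.ceil(max(bases)) if bases else 1.0
    return (float(old), 0.0)


def position_chart(
    species_tree: EvoTree,
    phenon_tree: EvoTree,
    rmap: RelationshipMap,
    settings: ChartSettings = ChartSettings(),
) -> Layout:
    """Assign every box, phenon segment, branch line and label an exact
    position.

    Boxes of a subtree occupy disjoint x extents; phenon slots are laid
    left to right inside their box at the group order; a phenon split
    across boxes gets one x per box.  Species branch lines run at the
    child's base age from the parent box's right side to the child's box
    center; in-box phenon branches run from the parent segment's x to the
    child's.
    """
    window = settings.window or _default_window(species_tree, phenon_tree)
    scale = AgeScale(
        old=window[0],
        young=window[1],
        units_per_myr=settings.units_per_myr,
        y_top=settings.margin,
    )
    layout = Layout(scale=scale, settings=settings)
    memo: dict[str, float] = {}

    def place(species: str, x_left: float) -> None:
        rng = species_tree.ranges[species]
        own = box_inner_width(rmap.group(species), settings)
        box = LayoutBox(
            species=species,
            x_left=x_left,
            x_right=x_left + own,
            y_top=scale.y(rng.top_age),
            y_bottom=scale.y(rng.base_age),
            top_age=rng.top_age,
            base_age=rng.base_age,
            style_runs=style_segments(rng),
            color=rng.color,
            popup=rng.popup,
            still_living=rng.still_living,
        )
        layout.boxes[species] = box
        # phenon slots, left to right in group order
        x = x_left + settings.box_padding
        for seg in rmap.group(species):
            w = slot_width(seg, settings)
            layout.segment_x[(seg.phenon_name, species)] = x + w / 2.0
            x += w + settings.slot_gap
        # children to the right, in branch authoring order
        child_x = x_left + own + settings.sibling_gap
        for child in species_tree.children_of(species):
            place(child, child_x)
            b = species_tree.branch_to(child)
            layout.species_branches.append(
                (
                    species,
                    child,
                    b.age,
                    box.x_right,
                    layout.boxes[child].x_center,
                    b.color,
                    b.style,
                    b.visible,
                )
            )
            child_x += subtree_width(child, species_tree, rmap, settings, memo) + settings.sibling_gap

    roots = sorted(species_tree.roots, key=lambda n: -species_tree.ranges[n].base_age)
    cursor = settings.margin + settings.axis_width
    for root in roots:
        place(root, cursor)
        cursor += subtree_width(root, species_tree, rmap, settings, memo) + settings.sibling_gap

    # in-box phenon branches (the connected subtrees within each box)
    hosted = layout.segment_x
    for b in phenon_tree.branches:
        for species in rmap.species_order:
            key_p, key_c = (b.parent, species), (b.child, species)
            if key_p in hosted and key_c in hosted:
                segs = {s.phenon_name: s for s in rmap.group(species)}
                p, c = segs[b.parent], segs[b.child]
                if (
                    p.young_age - 1e-9 <= b.age <= p.old_age + 1e-9
                    and c.young_age - 1e-9 <= b.age <= c.old_age + 1e-9
                ):
                    layout.phenon_branches.append(
                        (b.parent, b.child, species, b.age, hosted[key_p], hosted[key_c], b.color, b.style, b.visible)
                    )
    layout.width = (cursor - settings.sibling_gap if roots else cursor) + settings.margin
    layout.height = scale.y_bottom + settings.margin
    return layout


@dataclass
class ComponentLayout:
    """Positioned classic range-line tree (no boxes)."""

    scale: AgeScale
    settings: ChartSettings
    #: range name -> x of the vertical line
    range_x: dict[str, float] = field(default_factory=dict)
    branches: list[tuple] = field(default_factory=list)  # (parent, child, age, x_from, x_to, color, style, visible)
    width: float = 0.0
    height: float = 0.0


def position_component_tree(
    tree: EvoTree, settings: ChartSettings = ChartSettings()
) -> ComponentLayout:
    """Classic evolutionary-tree layout: each range a vertical line in its
    own label-wide slot, children to the right of the parent, the same
    summed-width recursion as for boxes."""
    window = settings.window or _default_window(tree, EvoTree())
    scale = AgeScale(
        old=window[0], young=window[1], units_per_myr=settings.units_per_myr, y_top=settings.margin
    )
    cl = ComponentLayout(scale=scale, settings=settings)

    def own_width(name: str) -> float:
        from .datapack_io import split_display_label

        display = split_display_label(name)[0]
        label_w = len(display) * settings.font_size_phenon * settings.label_char_factor
        return max(label_w if settings.show_labels else 0.0, settings.min_slot_width)

    memo: dict[str, float] = {}

    def width(name: str) -> float:
        if name in memo:
            return memo[name]
        w = own_width(name) + sum(
            settings.sibling_gap + width(c) for c in tree.children_of(name)
        )
        memo[name] = w
        return w

    def place(name: str, x_left: float) -> None:
        x = x_left + own_width(name) / 2.0
        cl.range_x[name] = x
        child_x = x_left + own_width(name) + settings.sibling_gap
        for child in tree.children_of(name):
            place(child, child_x)
            b = tree.branch_to(child)
            cl.branches.append(
                (name, child, b.age, x, cl.range_x[child], b.color, b.style, b.visible)
            )
            child_x += width(child) + settings.sibling_gap

    roots = sorted(tree.roots, key=lambda n: -tree.ranges[n].base_age)
    cursor = settings.margin + settings.axis_width
    for root in roots:
        place(root, cursor)
        cursor += width(root) + settings.sibling_gap
    cl.width = (cursor - settings.sibling_gap if roots else cursor) + settings.margin
    cl.height = scale.y_bottom + settings.margin
    return cl


def load_settings(path: str) -> ChartSettings:
    """Read :class:`ChartSettings` overrides from a YAML key-value file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "ordering" in data:
        data["ordering"] = OrderMode(data["ordering"])
    if "window" in data and data["window"] is not None:
        data["window"] = tuple(data["window"])
    if "background_bands" in data:
        data["background_bands"] = tuple(tuple(b) for b in data["background_bands"])
    return replace(ChartSettings(), **data)
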