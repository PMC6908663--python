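"""Validated species and phenon tree structures built from datapack rows.

Every taxon is a time range: an ordered series of dated points from its
first-appearance datum (FAD, the BASE of the range, oldest age) to its
last-appearance datum (LAD, the TOP, youngest age).  A range whose TOP row
carries the ``phenon`` flag is a phenon (morphotaxon) and names the species
in which its range ends; all other ranges are species lineages.  Branch rows
connect parent to child at a dated branch point; a child originates exactly
at its branch age.  Both trees may be forests — disconnected subtrees and
isolated ranges are retained as extra roots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datapack_io import (
    COL_B,
    COL_C,
    COL_D,
    COL_E,
    COL_F,
    COL_G,
    COL_H,
    COL_I,
    COL_J,
    COL_K,
    Datapack,
    RowKind,
)

__all__ = [
    "AGE_TOL",
    "RangePoint",
    "TaxonRange",
    "Branch",
    "EvoTree",
    "TreeValidationError",
    "ValidationIssue",
    "build_trees",
    "validate_datapack",
    "resolve_colors",
    "style_segments",
    "parse_color",
    "to_newick",
]

#: absolute tolerance for all age comparisons, Ma
AGE_TOL = 1e-9

#: abundance tokens that mark range extremities rather than line styles
_MARKER_TOKENS = {"top", "base", ""}

_NAMED_COLORS = {
    "black": "#000000",
    "white": "#ffffff",
    "red": "#ff0000",
    "green": "#008000",
    "blue": "#0000ff",
    "mediumblue": "#0000cd",
    "lightblue": "#add8e6",
    "darkblue": "#00008b",
    "orange": "#ffa500",
    "purple": "#800080",
    "brown": "#a52a2a",
    "gray": "#808080",
    "grey": "#808080",
}


def parse_color(text: str) -> str | None:
    """Normalize a datapack colour cell to ``#rrggbb``.

    Accepts ``R/G/B`` integer triplets, ``#rrggbb`` hex, or a small set of
    colour names.  Empty or unrecognizable text yields ``None`` (inherit).
    """
    text = text.strip().lower()
    if not text:
        return None
    if text.startswith("#") and len(text) == 7:
        return text
    if "/" in text:
        parts = text.split("/")
        if len(parts) == 3 and all(p.strip().isdigit() for p in parts):
            r, g, b = (min(255, int(p)) for p in parts)
            return f"#{r:02x}{g:02x}{b:02x}"
    return _NAMED_COLORS.get(text)


@dataclass(frozen=True)
class RangePoint:
    """One dated point of a taxon range.

    The abundance token is the line style applying from this point toward
    the next younger point (``frequent``, ``common``, ``rare``,
    ``conjectured``, ``sample-only``, ...); ``TOP`` marks the
    last-appearance point and carries no style of its own.
    """

    age: float
    abundance: str = ""
    popup: str = ""

    def __post_init__(self) -> None:
        if not (self.age >= 0.0):  # also rejects NaN
            raise ValueError(f"range point age must be finite and >= 0 Ma, got {self.age}")


@dataclass
class TaxonRange:
    """A species or phenon time range: ordered points plus attributes."""

    name: str
    points: list[RangePoint]  # ordered old -> young
    is_phenon: bool = False
    terminal_species: str | None = None  # phena only: species in which the range ends
    color: str | None = None  # resolved inherited colour, set by resolve_colors
    branch_style: str | None = None  # dashed/dotted of the incoming branch
    image: str | None = None

    @property
    def base_age(self) -> float:
        """FAD / BASE — the oldest point age, Ma."""
        return self.points[0].age

    @property
    def top_age(self) -> float:
        """LAD / TOP — the youngest point age, Ma."""
        return self.points[-1].age

    @property
    def still_living(self) -> bool:
        return abs(self.top_age) <= AGE_TOL

    @property
    def popup(self) -> str:
        texts = [p.popup for p in self.points if p.popup]
        return "; ".join(texts)


@dataclass(frozen=True)
class Branch:
    parent: str
    child: str
    age: float
    visible: bool = True
    label: str = ""
    style: str | None = None  # dashed/dotted
    popup: str = ""
    color: str | None = None
    priority: str = ""
    line_number: int = 0


@dataclass(frozen=True)
class ValidationIssue:
    line_number: int
    message: str

    def __str__(self) -> str:
        where = f"line {self.line_number}: " if self.line_number else ""
        return where + self.message


class TreeValidationError(ValueError):
    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        super().__init__("; ".join(str(i) for i in issues))


@dataclass
class EvoTree:
    """A forest of taxon ranges connected by dated branches."""

    ranges: dict[str, TaxonRange] = field(default_factory=dict)
    branches: list[Branch] = field(default_factory=list)

    @property
    def parent_of(self) -> dict[str, str]:
        return {b.child: b.parent for b in self.branches}

    def children_of(self, name: str) -> list[str]:
        """Children in branch authoring order (the left-right order)."""
        return [b.child for b in self.branches if b.parent == name]

    def branch_to(self, child: str) -> Branch | None:
        for b in self.branches:
            if b.child == child:
                return b
        return None

    @property
    def roots(self) -> list[str]:
        withparent = {b.child for b in self.branches}
        return [name for name in self.ranges if name not in withparent]

    def preorder(self, roots: list[str] | None = None) -> list[str]:
        """Depth-first pre-order; children in branch authoring order."""
        out: list[str] = []
        for root in self.roots if roots is None else roots:
            stack = [root]
            while stack:
                node = stack.pop()
                out.append(node)
                stack.extend(reversed(self.children_of(node)))
        return out


def _collect_ranges(pack: Datapack, issues: list[ValidationIssue]) -> dict[str, TaxonRange]:
    """Group range-point rows by label; phenon TOP rows flag their range."""
    ranges: dict[str, TaxonRange] = {}
    for row in pack.rows:
        if row.kind is RowKind.BRANCH:
            continue
        name = row.cells[COL_B]
        point = RangePoint(
            age=row.age, abundance=row.cells[COL_D], popup=row.cells[COL_E]
        )
        rng = ranges.get(name)
        if rng is None:
            rng = TaxonRange(name=name, points=[])
            ranges[name] = rng
        rng.points.append(point)
        if row.kind is RowKind.PHENON_TOP:
            species = row.cells[COL_H]
            if rng.is_phenon and rng.terminal_species != species:
                issues.append(
                    ValidationIssue(
                        row.line_number,
                        f"phenon {name!r} names two terminal species "
                        f"({rng.terminal_species!r} and {species!r})",
                    )
                )
            rng.is_phenon = True
            rng.terminal_species = species
    for rng in ranges.values():
        rng.points.sort(key=lambda p: -p.age)
        ages = [p.age for p in rng.points]
        if len(set(ages)) != len(ages):
            issues.append(
                ValidationIssue(0, f"range {rng.name!r} has duplicate point ages")
            )
        if len(rng.points) < 2 or rng.base_age - rng.top_age <= AGE_TOL:
            issues.append(
                ValidationIssue(
                    0,
                    f"range {rng.name!r} has zero duration "
                    f"(needs distinct BASE and TOP ages)",
                )
            )
    return ranges


def _collect_branches(pack: Datapack) -> list[Branch]:
    branches = []
    for row in pack.rows:
        if row.kind is not RowKind.BRANCH:
            continue
        c = row.cells
        branches.append(
            Branch(
                parent=c[COL_B],
                child=c[COL_E],
                age=row.age,
                visible=c[COL_F].strip().lower() != "off",
                label=c[COL_G],
                style=c[COL_H].strip().lower() or None,
                popup=c[COL_I],
                color=parse_color(c[COL_J]),
                priority=c[COL_K],
                line_number=row.line_number,
            )
        )
    return branches


def _check_branches(
    ranges: dict[str, TaxonRange], branches: list[Branch], issues: list[ValidationIssue]
) -> list[Branch]:
    ok: list[Branch] = []
    seen_child: dict[str, int] = {}
    for b in branches:
        bad = False
        if b.parent not in ranges:
            issues.append(ValidationIssue(b.line_number, f"branch from unknown range {b.parent!r}"))
            bad = True
        if b.child not in ranges:
            issues.append(ValidationIssue(b.line_number, f"branch to unknown range {b.child!r}"))
            bad = True
        if bad:
            continue
        if ranges[b.parent].is_phenon != ranges[b.child].is_phenon:
            issues.append(
                ValidationIssue(
                    b.line_number,
                    f"branch {b.parent!r} -> {b.child!r} crosses between the species "
                    "and phenon trees",
                )
            )
            continue
        if b.child in seen_child:
            issues.append(
                ValidationIssue(
                    b.line_number,
                    f"range {b.child!r} has two parents ({seen_child[b.child]} was the first branch line)",
                )
            )
            continue
        seen_child[b.child] = b.line_number
        parent, child = ranges[b.parent], ranges[b.child]
        if not (parent.base_age + AGE_TOL >= b.age >= parent.top_age - AGE_TOL):
            issues.append(
                ValidationIssue(
                    b.line_number,
                    f"branch age {b.age} Ma outside parent range {b.parent!r} "
                    f"[{parent.top_age}, {parent.base_age}]",
                )
            )
            continue
        if abs(child.base_age - b.age) > AGE_TOL:
            issues.append(
                ValidationIssue(
                    b.line_number,
                    f"child {b.child!r} BASE {child.base_age} Ma does not equal its "
                    f"branch age {b.age} Ma (a child originates at its branch point)",
                )
            )
            continue
        ok.append(b)
    # cycle check: walk rootward from every node
    parent_of = {b.child: b.parent for b in ok}
    for name in ranges:
        seen = {name}
        cur = name
        while cur in parent_of:
            cur = parent_of[cur]
            if cur in seen:
                issues.append(ValidationIssue(0, f"cycle through range {name!r}"))
                break
            seen.add(cur)
    return ok


def validate_datapack(pack: Datapack) -> list[ValidationIssue]:
    """Machine-readable validation report for a parsed datapack."""
    issues: list[ValidationIssue] = []
    ranges = _collect_ranges(pack, issues)
    branches = _check_branches(ranges, _collect_branches(pack), issues)
    for rng in ranges.values():
        if rng.is_phenon and rng.terminal_species not in ranges:
            issues.append(
                ValidationIssue(
                    0,
                    f"phenon {rng.name!r} names unknown terminal species "
                    f"{rng.terminal_species!r}",
                )
            )
        elif rng.is_phenon and ranges[rng.terminal_species].is_phenon:
            issues.append(
                ValidationIssue(
                    0,
                    f"phenon {rng.name!r} names another phenon "
                    f"({rng.terminal_species!r}) as its terminal species",
                )
            )
    del branches
    return issues


def build_trees(pack: Datapack) -> tuple[EvoTree, EvoTree]:
    """Partition a datapack into validated (species_tree, phenon_tree).

    Ranges are partitioned by the phenon TOP marker; branches are attached
    within each partition.  Raises :class:`TreeValidationError` aggregating
    every violation (cycles, double parents, unknown names, branch-age
    mismatches, cross-tree branches) with line numbers where known.
    """
    issues = validate_datapack(pack)
    if issues:
        raise TreeValidationError(issues)
    issues = []
    ranges = _collect_ranges(pack, issues)
    branches = _check_branches(ranges, _collect_branches(pack), issues)
    species = EvoTree(
        ranges={n: r for n, r in ranges.items() if not r.is_phenon},
        branches=[b for b in branches if not ranges[b.parent].is_phenon],
    )
    phena = EvoTree(
        ranges={n: r for n, r in ranges.items() if r.is_phenon},
        branches=[b for b in branches if ranges[b.parent].is_phenon],
    )
    for tree in (species, phena):
        for b in tree.branches:
            if b.style:
                tree.ranges[b.child].branch_style = b.style
    return species, phena


def resolve_colors(tree: EvoTree, default: str = "#000000") -> dict[str, str]:
    """Colour inheritance: a colour assigned to a branch is inherited by the
    child and all its descendants until a later branch assigns a new one;
    roots with no assignment anywhere get the default.

    Sets ``TaxonRange.color`` and returns the name -> colour mapping.
    Idempotent and independent of branch order.
    """
    colors: dict[str, str] = {}
    branch_color = {b.child: b.color for b in tree.branches}
    parent_of = tree.parent_of

    def resolve(name: str) -> str:
        if name in colors:
            return colors[name]
        own = branch_color.get(name)
        if own:
            colors[name] = own
        elif name in parent_of:
            colors[name] = resolve(parent_of[name])
        else:
            colors[name] = default
        return colors[name]

    for name in tree.ranges:
        tree.ranges[name].color = resolve(name)
    return colors


def style_segments(rng: TaxonRange) -> list[tuple[float, float, str]]:
    """Cut a range into contiguous styled intervals ``(old, young, token)``.

    The style of each interval is the abundance token of the point at its
    older end; marker tokens (``TOP``/``BASE``/empty) carry the previous
    style forward, or the empty token if there is none (the renderer then
    applies the tree's default style).  Intervals cover exactly
    ``[top_age, base_age]`` and share junction ages.
    """
    segs: list[tuple[float, float, str]] = []
    current = ""
    for older, younger in zip(rng.points, rng.points[1:]):
        token = older.abundance.strip()
        if token.lower() in _MARKER_TOKENS:
            token = current
        current = token
        if segs and segs[-1][2] == token:
            old, _, _ = segs.pop()
            segs.append((old, younger.age, token))
        else:
            segs.append((older.age, younger.age, token))
    return segs


def to_newick(tree: EvoTree) -> str:
    """Export the forest topology as newick, branch lengths in Myr
    (parent branch age minus child branch age / range top).  Interop only."""

    def node(name: str, origin: float) -> str:
        kids = tree.children_of(name)
        length = origin - tree.ranges[name].top_age
        label = name.replace(" ", "_").replace("(", "").replace(")", "")
        if not kids:
            return f"{label}:{length:g}"
        parts = ",".join(node(k, tree.branch_to(k).age) for k in kids)
        return f"({parts}){label}:{length:g}"

    return ";".join(node(r, tree.ranges[r].base_age) for r in tree.roots) + ";"
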