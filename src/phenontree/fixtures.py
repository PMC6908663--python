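"""Deterministic datapack generators.

``worked_example_fixture`` builds the canonical worked example: a black ancestor
giving rise to a green descendant *Aa*, in turn to a blue group (*Bb*
ancestral to *Be* and *Bf*), with a seven-phenon tree whose ranges cross
the species origins.  Only *Aa*'s style ages (frequent 13-5 Ma,
conjectured 5-0 Ma) are fixed by the source chart; the remaining ages are
this package's canonical convention chosen to reproduce the drawn topology
and the published relationship map.

``random_fixture`` generates valid datapacks of any size by recursive
budding of species inside an age window and placing phena inside species
with a controlled probability of crossing rootward over the species'
origin, so the splitting machinery is exercised.  Ages are drawn on a
0.01 Myr grid to avoid floating ties while still exercising the tolerance
path.  Every generated datapack passes validation and completes the full
pipeline by construction.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .datapack_io import Datapack, DataRow, RowKind

__all__ = ["FixtureSpec", "worked_example_fixture", "random_fixture"]

_GRID = 0.01


def _row(kind: RowKind, *cells: str, line: int = 0) -> DataRow:
    return DataRow(kind, tuple(cells), line)


def _range_point(label: str, age: float, abundance: str = "", popup: str = "") -> DataRow:
    return _row(RowKind.RANGE_POINT, label, f"{age:g}", abundance, popup)


def _top(label: str, age: float, popup: str = "") -> DataRow:
    return _row(RowKind.RANGE_POINT, label, f"{age:g}", "TOP", popup)


def _phenon_top(label: str, age: float, species: str, popup: str = "") -> DataRow:
    return _row(RowKind.PHENON_TOP, label, f"{age:g}", "TOP", popup, "", "phenon", species)


def _branch(
    parent: str, age: float, child: str, color: str = "", style: str = "", label: str = ""
) -> DataRow:
    return _row(RowKind.BRANCH, parent, f"{age:g}", "branch", child, "on", label, style, "", color)


def worked_example_fixture(variant: str = "I") -> Datapack:
    """The canonical worked example.

    Variant ``"I"``: one species tree (ancestor, Aa, Bb, Be, Bf) and one
    connected phenon tree (phenon, a, b, c, d, e, f).  Variant ``"III"``
    adds a disconnected phenon tree (h -> i) and an isolated phenon range
    (g) along the Bb-Be lineage series, each staying within a single box.
    """
    variant = str(variant).upper()
    if variant not in {"I", "III"}:
        raise ValueError(f"unknown variant {variant!r} (expected 'I' or 'III')")
    rows: list[DataRow] = []
    # species tree: ancestor -> Aa -> Bb -> {Be, Bf}
    rows += [_range_point("ancestor", 18, "frequent"), _top("ancestor", 13)]
    rows += [
        _range_point("Aa", 13, "frequent"),
        _range_point("Aa", 5, "conjectured"),
        _top("Aa", 0),
    ]
    rows += [_range_point("Bb", 10, "frequent"), _top("Bb", 2)]
    rows += [_range_point("Be", 6, "frequent"), _top("Be", 0)]
    rows += [_range_point("Bf", 4, "frequent"), _top("Bf", 1)]
    rows += [
        _branch("ancestor", 13, "Aa", color="green"),
        _branch("Aa", 10, "Bb", color="mediumblue"),
        _branch("Bb", 6, "Be", color="lightblue"),
        _branch("Bb", 4, "Bf", color="darkblue"),
    ]
    # phenon tree: phenon -> a -> b -> c -> d -> {e, f}
    rows += [_range_point("phenon", 18, "frequent"), _phenon_top("phenon", 13, "ancestor")]
    rows += [
        _range_point("a", 13, "frequent"),
        _range_point("a", 5, "conjectured"),
        _phenon_top("a", 0, "Aa"),
    ]
    rows += [_range_point("b", 12, "frequent"), _phenon_top("b", 8, "Bb")]
    rows += [_range_point("c", 9, "frequent"), _phenon_top("c", 3, "Be")]
    rows += [_range_point("d", 8, "frequent"), _phenon_top("d", 0, "Be")]
    rows += [_range_point("e", 4, "frequent"), _phenon_top("e", 0, "Be")]
    rows += [_range_point("f", 7, "frequent"), _phenon_top("f", 1, "Bf")]
    rows += [
        _branch("phenon", 13, "a", color="green"),
        _branch("a", 12, "b", color="mediumblue"),
        _branch("b", 9, "c"),
        _branch("c", 8, "d"),
        _branch("d", 4, "e", color="lightblue"),
        _branch("d", 7, "f", color="darkblue"),
    ]
    if variant == "III":
        # disconnected additions along the Bb-Be lineage series, in black
        rows += [_range_point("g", 5, "frequent"), _phenon_top("g", 3, "Be")]
        rows += [_range_point("h", 9, "frequent"), _phenon_top("h", 7, "Bb")]
        rows += [_range_point("i", 8, "frequent"), _phenon_top("i", 6.5, "Bb")]
        rows += [_branch("h", 8, "i")]
    name = "integrated species-phenon example" + ("" if variant == "I" else " (iii)")
    return Datapack(column_name=name, rows=rows)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the randomized generator.

    ``crossing_probability`` is the chance that a phenon's origin is pushed
    rootward past its terminal species' FAD (forcing at least one split);
    ``living_fraction`` the chance a species (and any phenon ending in it at
    its TOP) extends to the present.  ``depth_bounds`` caps the species-tree
    depth.
    """

    seed: int = 0
    n_species: int = 10
    n_phena: int = 25
    depth_bounds: tuple[int, int] = (1, 6)
    age_window: tuple[float, float] = (30.0, 0.0)
    crossing_probability: float = 0.5
    living_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_phena < 0:
            raise ValueError("n_phena must be >= 0")
        if not (0.0 <= self.crossing_probability <= 1.0):
            raise ValueError("crossing_probability must be in [0, 1]")
        if self.age_window[0] <= self.age_window[1]:
            raise ValueError("age window must be (old, young) with old > young")


def _grid_choice(rng: random.Random, low: float, high: float) -> float | None:
    """A grid age in [low, high]; None when the interval holds no grid point."""
    lo = math.ceil(low / _GRID - 1e-9)
    hi = math.floor(high / _GRID + 1e-9)
    if hi < lo:
        return None
    return round(rng.randint(lo, hi) * _GRID, 2)


def _grid_between(rng: random.Random, low: float, high: float) -> float | None:
    """A grid age strictly inside (low, high)."""
    lo = math.floor(low / _GRID + 1e-9) + 1
    hi = math.ceil(high / _GRID - 1e-9) - 1
    if hi < lo:
        return None
    return round(rng.randint(lo, hi) * _GRID, 2)


@dataclass
class _Sp:
    name: str
    base: float
    top: float
    parent: str | None
    depth: int


def random_fixture(spec: FixtureSpec) -> Datapack:
    """Generate a reproducible valid datapack per :class:`FixtureSpec`."""
    rng = random.Random(spec.seed)
    old, young = spec.age_window
    colors = ["", "green", "mediumblue", "lightblue", "darkblue", "red", "orange", "purple"]
    styles = ["frequent", "frequent", "common", "rare", "conjectured"]

    species: list[_Sp] = []
    root_top = (
        0.0 if rng.random() < spec.living_fraction else round(
            _grid_between(rng, young, old * 0.6) or young, 2
        )
    )
    species.append(_Sp("s1", round(old, 2), root_top, None, 1))
    tries = 0
    while len(species) < spec.n_species and tries < spec.n_species * 200:
        tries += 1
        parent = rng.choice([s for s in species if s.depth < spec.depth_bounds[1]] or species)
        if parent.depth >= spec.depth_bounds[1]:
            continue
        base = _grid_between(rng, parent.top, parent.base)
        if base is None:
            continue
        if rng.random() < spec.living_fraction:
            top = 0.0
        else:
            top = _grid_between(rng, young, base)
            if top is None:
                continue
        if base - top < 2 * _GRID - 1e-9:
            continue
        species.append(_Sp(f"s{len(species) + 1}", base, top, parent.name, parent.depth + 1))

    by_name = {s.name: s for s in species}

    def chain(name: str) -> list[_Sp]:
        out = [by_name[name]]
        while out[-1].parent is not None:
            out.append(by_name[out[-1].parent])
        return out

    phena: list[tuple[str, float, float, str]] = []  # (name, base, top, terminal species)
    tries = 0
    while len(phena) < spec.n_phena and tries < spec.n_phena * 200 + 200:
        tries += 1
        host = rng.choice(species)
        top = _grid_choice(rng, host.top, host.base - _GRID)
        if top is None or top >= host.base - 1e-9:
            continue
        if host.top == 0.0 and rng.random() < spec.living_fraction:
            top = 0.0
        cross = rng.random() < spec.crossing_probability and host.parent is not None
        if cross:
            anc = chain(host.name)
            target = rng.choice(anc[1:])
            base = _grid_between(rng, host.base, target.base)
            if base is None:
                base = target.base  # origin exactly at an ancestor's FAD (a tie)
        else:
            # may tie exactly with the host's FAD (coincident origination)
            base = host.base if rng.random() < 0.15 else _grid_between(rng, top, host.base)
            if base is None:
                base = host.base
        if base - top < _GRID - 1e-9:
            continue
        phena.append((f"p{len(phena) + 1}", round(base, 2), round(top, 2), host.name))

    # connect some phena into trees: child's BASE must fall inside the parent
    phenon_parent: dict[str, tuple[str, float]] = {}
    for i, (name, base, top, _) in enumerate(phena):
        if rng.random() < 0.5:
            candidates = [
                p
                for p in phena[:i]
                if p[2] <= base <= p[1] and p[0] not in {name}
            ]
            if candidates:
                parent = rng.choice(candidates)
                phenon_parent[name] = (parent[0], base)

    rows: list[DataRow] = []
    for s in species:
        style = rng.choice(styles)
        rows.append(_range_point(s.name, s.base, style))
        mid = _grid_between(rng, s.top, s.base)
        if mid is not None and rng.random() < 0.3:
            rows.append(_range_point(s.name, mid, rng.choice(styles)))
        rows.append(_top(s.name, s.top))
    for s in species:
        if s.parent is not None:
            rows.append(_branch(s.parent, s.base, s.name, color=rng.choice(colors)))
    for name, base, top, terminal in phena:
        rows.append(_range_point(name, base, rng.choice(styles)))
        mid = _grid_between(rng, top, base)
        if mid is not None and rng.random() < 0.3:
            rows.append(_range_point(name, mid, rng.choice(styles)))
        rows.append(_phenon_top(name, top, terminal))
    for child, (parent, age) in phenon_parent.items():
        rows.append(_branch(parent, age, child, color=rng.choice(colors)))
    return Datapack(column_name=f"random fixture seed {spec.seed}", rows=rows)
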