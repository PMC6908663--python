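"""Independent brute-force oracles used to cross-check the package.

These work directly on raw datapack rows and plain interval arithmetic,
never calling the implementation paths they check.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

from phenontree.datapack_io import COL_B, COL_C, COL_D, COL_E, COL_H, Datapack, RowKind

TOL = 1e-9


def raw_tables(pack: Datapack):
    """(species intervals, phenon intervals, terminal species, species
    parent map, phenon branch list) read straight off the rows."""
    ages: dict[str, list[float]] = {}
    terminal: dict[str, str] = {}
    branches: list[tuple[str, str, float]] = []
    for row in pack.rows:
        if row.kind is RowKind.BRANCH:
            branches.append((row.cells[COL_B], row.cells[COL_E], float(row.cells[COL_C])))
            continue
        ages.setdefault(row.cells[COL_B], []).append(float(row.cells[COL_C]))
        if row.kind is RowKind.PHENON_TOP:
            terminal[row.cells[COL_B]] = row.cells[COL_H]
    intervals = {name: (max(a), min(a)) for name, a in ages.items()}  # (base, top)
    species = {n: iv for n, iv in intervals.items() if n not in terminal}
    phena = {n: iv for n, iv in intervals.items() if n in terminal}
    sp_parent = {c: p for p, c, _ in branches if p in species and c in species}
    ph_branches = [(p, c, a) for p, c, a in branches if p in phena]
    return species, phena, terminal, sp_parent, ph_branches


def oracle_chain(name: str, parent_of: dict[str, str]) -> list[str]:
    chain = [name]
    while chain[-1] in parent_of:
        chain.append(parent_of[chain[-1]])
    return chain


def oracle_split(
    base: float,
    top: float,
    terminal: str,
    species: dict[str, tuple[float, float]],
    parent_of: dict[str, str],
) -> list[tuple[str, float, float]]:
    """Interval intersection along the ancestral chain: cut the phenon
    interval at every chain species' FAD strictly inside it and host each
    piece in the species reached after crossing the cuts below it.
    Returns (host, old, young) ordered old -> young."""
    chain = oracle_chain(terminal, parent_of)
    cuts = sorted(
        {species[s][0] for s in chain if top + TOL < species[s][0] < base - TOL}
    )
    bounds = [top] + cuts + [base]
    segments = []
    i = 0
    for young, old in zip(bounds, bounds[1:]):
        segments.append((chain[i], old, young))
        while i + 1 < len(chain) and species[chain[i]][0] <= old + TOL:
            i += 1
    return list(reversed(segments))


def oracle_box_components(
    in_box: list[str],
    box_segments: dict[str, tuple[float, float]],
    ph_branches: list[tuple[str, str, float]],
) -> list[frozenset[str]]:
    """Connected components of the induced segment graph inside one box:
    an edge joins parent and child phena when both have a segment here and
    the branch age lies inside both segment intervals."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(in_box)
    for p, c, age in ph_branches:
        if p in box_segments and c in box_segments:
            (po, py), (co, cy) = box_segments[p], box_segments[c]
            if py - TOL <= age <= po + TOL and cy - TOL <= age <= co + TOL:
                g.add_edge(p, c)
    return [frozenset(comp) for comp in nx.connected_components(g)]


def svg_age_scale(svg_text: str):
    """Recover the age <-> y map a rendered chart embeds in <metadata>."""
    root = ET.fromstring(svg_text)
    ns = "{http://www.w3.org/2000/svg}"
    meta = root.find(f"{ns}metadata")
    params = json.loads(meta.text)["age_scale"]

    def to_age(y: float) -> float:
        return params["young"] + (y - params["y_top"]) / params["units_per_myr"]

    return root, ns, to_age
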