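# phenontree

Integrated species–phenon trees: visualize infraspecific diversity within
fossil lineages through deep time.

Paleontological systematics routinely works with two loosely coupled,
time-calibrated evolutionary trees for the same organisms: a tree of
**species lineages** (reconstructed stratophenetically, ancestor to
descendant) and a tree of **phena** — informal morphotaxa whose ranges may
persist across species boundaries. `phenontree` merges the two into one
chart: each species range is expanded into a translucent **species box**
spanning its time range, each phenon range is algorithmically broken at
every species origin it crosses and the parts transferred rootward along
the species' ancestral chain, and the result is rendered as a standalone
SVG range chart against geologic time, with guide symbols marking true
origins, extinctions and still-living tops versus artificial breaks
between boxes. It is aimed at micropaleontologists and anyone needing to
draw two nested but loosely coupled trees — e.g. morphospecies within
lineages of planktonic foraminifera — from plain tab-delimited range data.

## The method in brief

Every taxon is a range from its first-appearance datum (FAD/BASE, oldest
age in Ma) to its last-appearance datum (LAD/TOP). The only datum linking
the trees is, per phenon, the species in which its range **ends**. Given
terminal species `s₀` with ancestral chain `s₀, s₁, …, sₖ` (FADs strictly
increasing rootward), a phenon spanning `[top, base]` is cut at every FAD
`f(sᵢ)` with `top < f(sᵢ) < base`; the piece between consecutive cuts is
hosted by the chain species whose interval contains it, the piece count
being (cuts strictly inside the open interval) + 1. Pieces exactly tile
the original range; each break produces a matched top/bottom chevron pair
at the cut age in the two adjacent boxes. Grouping pieces by host species
yields the one-to-many **species–phenon relationship map**, which then
determines every box's width (slots for its phenon labels/images plus
gaps and padding; empty boxes get a minimum width) and, via a recursive
subtree-width computation, a collision-free chart layout.

## Worked example

The built-in fixture reproduces the canonical example: a black ancestor
(18–13 Ma) giving rise to green *Aa* (13–0 Ma, still living), in turn to
a blue group (*Bb* 10–2 Ma, ancestral to *Be* 6–0 Ma and *Bf* 4–1 Ma),
with a seven-phenon tree inside.

```sh
phenontree fixtures example-i -o example.txt
phenontree validate example.txt
phenontree map example.txt
phenontree render example.txt -o example.svg
```

prints

```
OK: 5 species ranges, 7 phenon ranges, 10 branches
relationship_id	species	group_size	phenon	relationship
1-1	ancestor	1	phenon	ancestor <- phenon
2-1	Aa	2	a	Aa <- a
2-2	Aa	2	b	Aa <- b
3-1	Bb	4	b	Bb <- b
3-2	Bb	4	c	Bb <- c
3-3	Bb	4	d	Bb <- d
3-4	Bb	4	f	Bb <- f
4-1	Be	3	c	Be <- c
4-2	Be	3	d	Be <- d
4-3	Be	3	e	Be <- e
5-1	Bf	1	f	Bf <- f
```

Read the table as: phenon *b* (12–8 Ma) ends inside *Bb* but predates
*Bb*'s origin at 10 Ma, so it is broken into two parts — the older drawn
in the *Aa* box, the younger in *Bb* — and appears in both groups.
Likewise *c* and *d* are shared between *Bb* and *Be*, and *f* between
*Bb* and *Bf*; inside *Be* the transfers leave two disconnected subtrees
({*c*} and the tree rooted at *d*). `example.svg` shows the boxes filled
with their inherited colours at 25% opacity, *Aa*'s borders "frequent"
(solid, thick) for the 8 Myr up from its base and "conjectured" (dashed)
for the 5 Myr down from its top, and red guide symbols at every segment
extremity.

`phenontree render` also accepts `--mode species|phenon` to draw either
component tree classically, `--order first|last|alpha` for in-box
ordering, `--window OLD,YOUNG`, `--no-labels`, and `--config
settings.yaml` for chart settings (scale, fonts, gaps, opacity,
background bands; see `phenontree.layout.ChartSettings`).

As a library:

```python
from phenontree import (build_trees, compute_relationship_map, worked_example_fixture,
                        position_chart, render, resolve_colors)

species, phena = build_trees(worked_example_fixture("I"))
resolve_colors(species); resolve_colors(phena)
rmap = compute_relationship_map(species, phena)
svg = render(position_chart(species, phena, rmap), rmap)
```

Randomized valid datapacks of any size are available from
`phenontree.fixtures.random_fixture` (or `phenontree fixtures random`);
the published 210-species / 339-phenon planktonic-foraminifer datapack
(ANU Data Commons anudc:5981) can be dropped into `data/case_study/` and
used directly.

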