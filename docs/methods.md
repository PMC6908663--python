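# Methods

## The integrated species–phenon tree

Paleontological practice reconstructs two loosely coupled evolutionary
trees for the same organisms: a tree of **species lineages** traced
stratophenetically through time, and a tree of **phena** — informal,
morphologically defined fossil taxa that may persist across species
boundaries. Both are time-calibrated range charts: every taxon is a time
range from its first-appearance datum (FAD, or BASE, the oldest age) to
its last-appearance datum (LAD, or TOP, the youngest), and branches are
dated ancestor–descendant connections.

The integrated tree merges the two by

1. expanding each species range into a rectangular **species box** spanning
   its exact time range,
2. breaking each phenon range at every species origin it crosses and
   transferring the older parts rootward along the species' ancestral
   chain, and
3. drawing the broken parts inside their host boxes, with **guide
   symbols** at every extremity distinguishing a true range origin,
   extinction or still-living top from an artificial break between boxes.

The single datum coupling the trees is, per phenon, the name of the
species in which its range **ends** (carried on the phenon's TOP row in
the datapack). Everything else is derived: walking the ancestral chain of
that terminal species rootward, the phenon interval is cut at every chain
species' FAD that lies strictly inside it; the piece between two cuts is
hosted by the chain species whose interval contains it. The cut ages are
duplicated into both adjacent pieces (closed intervals — the drawn lines
abut), style runs of the phenon are re-cut at the same ages, and all other
attributes (colour, pop-ups, image references) are duplicated onto every
piece.

Grouping the pieces by host species gives the one-to-many
**species–phenon relationship map**, the central data structure: it is
what determines each box's width, and it is exported as a tab-delimited
table (`phenontree map`). Relationship ids are `<species>-<member>` with
species numbered by a deterministic pre-order traversal of the species
tree (roots oldest-first) and members by their in-box order; ids are
strictly sequential within a group.

### Tie and error conventions

All age comparisons use an absolute tolerance of 1e-9 Ma.

* Phenon FAD exactly at a species FAD (common in real data, where many
  phena originate with their species): no zero-length part is emitted —
  the origin sits at that box's base.
* Phenon TOP exactly at its terminal species' FAD: the whole range belongs
  to the ancestor, so the terminal species must name the ancestor;
  anything else is a "phenon ends outside its species" error, never a
  silent fix.
* A phenon outliving its host species, or predating the FAD of the chain's
  root, is an error, not a clamp.
* Two consecutive chain species sharing a FAD (a branch exactly at the
  parent's own origin) would produce a zero-length part in the
  intermediate species; it is skipped instead.
* Zero-duration ranges, duplicate point ages, duplicate labels used as two
  taxa, children with two parents, cycles, branch ages outside the parent
  range, a child whose FAD differs from its branch age, and branches
  crossing between the species and phenon partitions are all validation
  errors reported with line numbers.

### Disconnected trees and in-box subtrees

Both inputs may be forests; isolated phenon ranges and disconnected
phenon trees are retained as extra roots and placed in their boxes like
any other. Splitting also *creates* disconnection: inside one box, two
segments are connected only where the phenon tree's branch age lies
within the box's time extent and within both segments' intervals there;
every other segment roots its own subtree. Root subtrees within a box
(and tree roots within a column) are ordered by First Occurrence (oldest
FAD first; the default), Last Occurrence, or Alphabetic order of the
display label; sorting is stable, and connected subtrees keep the phenon
tree's authoring (left–right) order internally.

## Layout

Vertical position is a linear map from age to canvas y (younger at the
top, `units_per_myr` canvas units per Myr; default 20). The plotted
window defaults to [max FAD rounded up to a whole Myr, 0] and is
configurable.

Horizontal position comes from a recursive width computation:

* a **slot** for one phenon segment is the larger of its display-label
  estimate (character count × phenon font size × 0.6, a deliberate
  font-metric-free estimate so layout is deterministic), its thumbnail
  width when images are shown, and a minimum slot width;
* a **box** is its slots plus inter-slot gaps plus padding both sides, or
  a minimum box width when the species hosts no phena;
* a **subtree** is the box plus all child subtrees plus sibling gaps,
  children laid out to the right of the parent box in branch authoring
  order (never permuted).

Summing rather than maximizing over children is a deliberate choice: a
parent lineage normally persists alongside its descendants, so parent and
child boxes overlap in time and may never share horizontal space. The sum
guarantees a collision-free chart for every valid input (property-tested
across 1000 randomized datapacks); the cost is a wider chart than an
overlap-aware packing could achieve for the minority of branches where
the parent ends before the child begins. Species branch lines run
horizontally at the child's FAD from the parent box's right side to the
child box's center; a split phenon gets an independently assigned slot in
each box it occupies (no cross-box x alignment).

## Rendering

The chart is standalone SVG 1.1. Each species box is a rect filled with
the lineage's inherited colour at `box_alpha` opacity (default 0.25,
strictly between 0 and 1 so the phenon lines and labels inside stay
legible) plus four border lines, the sides cut into runs so that each
carries the range's per-interval line style — a species that is
"frequent" for its older 8 Myr and "conjectured" for its younger 5 Myr
shows exactly those runs up its sides. Colours are inherited down the
tree from branch assignments until reassigned; unassigned roots default
to black.

Line styles are the abundance tokens: frequent = solid 2.0, common =
solid 1.0, rare = dotted, conjectured = dashed, sample-only = sparse
dots; unknown tokens fall back to "common" with a logged warning. The
species default ("frequent") is strictly thicker than the phenon default
("common"), which is what makes boxes visually dominate the lines inside
them. Guide symbols are drawn in a configurable accent colour (default
red): origin = horizontal tick, extinction = capped bar, still-living =
arrowhead at the present, break top / break bottom = open up/down
chevrons; the five shapes are this package's convention serving the
required five-way distinction. Pop-up texts become `<title>` elements;
the age axis ticks every `tick_interval` Myr; optional user-supplied
background bands substitute for a chronostratigraphic backdrop, which is
out of scope. The age-scale parameters are embedded as JSON in
`<metadata>` so y coordinates are invertible to ages (tested to 1e-6 Myr)
by any consumer.

`render_component_trees` draws either input tree classically (vertical
range lines, horizontal branches) for side-by-side comparison.

## The datapack dialect

Tab-delimited text; each data row carries spreadsheet columns B..K after
an ignored column-A field; an optional one-line header names the column.
Ages are decimal Ma. Trailing empty cells may be omitted; parse∘write is
the structural identity. The abundance vocabulary is open — tokens are
carried verbatim and only styled from the table above. Branch column F
("on"/"off") hides a branch when off; column K (priority) is carried but
not interpreted. Pop-up cells are never interpreted. Either tree's
topology can be exported as newick (branch lengths in Myr) for interop.

## The fixture generators

`worked_example_fixture` encodes the canonical worked example: species
ancestor(18–13) → Aa(13–0, still living; frequent 13–5, conjectured 5–0)
→ Bb(10–2) → {Be(6–0, still living), Bf(4–1)}, with a seven-phenon tree
whose branch ages and most range ages are this package's canonical
convention, chosen once so the drawn topology and the published
relationship map (groups of 1, 2, 4, 3 and 1 phena) are reproduced; only
Aa's 13/5/0 Ma styling ages are fixed by the source chart. Variant III
adds a disconnected phenon tree (h→i) and an isolated phenon (g) on the
Bb–Be series, each within a single box.

`random_fixture` emulates datapacks of arbitrary size: a species forest
grown by recursive budding inside a 30–0 Ma window (depth ≤ 6), phena
placed inside species with a controlled `crossing_probability` (default
0.5) of extending rootward past their species' FAD — including exact-FAD
ties, mirroring the frequent coincident originations in real datasets — a
`living_fraction` (default 0.2) reaching the present, 1–3 style points
per range, and optional phenon-tree connections. Ages are drawn on a
0.01 Myr grid to avoid floating-point ties while the 1e-9 tolerance path
is still exercised. Every generated datapack is valid by construction and
completes the full parse → build → map → layout → render pipeline.

What the generator does **not** emulate: real taxon name structure (and
thus realistic label widths), thumbnail images, heterogeneous pop-up
metadata, the empirical distribution of range durations and tree
imbalance, and datapacks with authoring errors. Passing tests therefore
demonstrate algorithmic correctness on valid inputs of realistic
structure, not robustness to the full messiness of hand-compiled data.

## Problem sizes and verification

The invariant suite runs 1000 randomized datapacks (4–12 species, 8–30
phena, the full pipeline each time, a few seconds in total) checking:
equivalence of the splitter with an independent brute-force
interval-intersection oracle; conservation (each phenon's parts exactly
tile its original interval); matched break-symbol pairs at equal ages;
collision-free layout (exhaustive pairwise box scan); parse/write
round-trip identity; and inversion of rendered y-extents to ages within
1e-6 Myr. The published 210-species / 339-phenon case-study datapack is
supported as an optional input (`data/case_study/`) but is not
redistributed here.

## Known limitations

* Box widths ignore the species label, which can overflow very narrow
  boxes; widen `min_box_width` if needed.
* No width minimization or sibling reordering; charts are wider than an
  optimal packing.
* No raster export, interactivity, or chronostratigraphic colour bands;
  SVG only, with pop-ups as static titles.
* A phenon can only transfer rootward along the ancestral chain; carrying
  a phenon into a budding descendant is expressed by authoring the
  terminal species accordingly.
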