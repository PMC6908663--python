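"""Standalone SVG output.

Species boxes are drawn as a translucent rect in the lineage's inherited
colour plus four border polylines, so each side can carry the range's
per-interval line styles (a box that is "frequent" for its older 8 Myr and
"conjectured" for its younger 5 Myr shows exactly those runs along its
sides).  Phenon segments are vertical lines in their own styles and
colours, capped with guide symbols: origin tick, extinction bar,
still-living arrowhead at the present, and open chevrons where a range
breaks between boxes.  Pop-up texts are embedded as SVG ``<title>``
elements; an age axis with Myr ticks and optional background interval
bands complete the chart.  The age-scale parameters are embedded as JSON
in the document ``<metadata>`` so any consumer can invert y back to age.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .integration import BaseSymbol, PhenonSegment, RelationshipMap, TopSymbol
from .layout import AgeScale, ChartSettings, Layout, position_component_tree
from .tree_model import EvoTree

__all__ = ["StyleSpec", "render", "render_component_trees"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StyleSpec:
    """Abundance token -> (stroke width, dash pattern or None).

    The species default token must render strictly thicker than the phenon
    default so box borders stand out from the phenon lines inside them.
    """

    tokens: dict[str, tuple[float, str | None]] = field(
        default_factory=lambda: {
            "frequent": (2.0, None),
            "common": (1.0, None),
            "rare": (1.0, "1 3"),
            "conjectured": (1.0, "5 3"),
            "sample-only": (1.0, "1 5"),
        }
    )
    fallback: str = "common"
    symbol_size: float = 5.0

    def get(self, token: str, default_token: str) -> tuple[float, str | None]:
        token = token.strip().lower() or default_token
        if token not in self.tokens:
            logger.warning("unknown abundance token %r; styling as %r", token, self.fallback)
            token = self.fallback
        return self.tokens[token]


def _fmt(value: float) -> str:
    return f"{value:.6f}"


def _safe_id(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-._" else "_" for ch in name)


def _line(
    parent: ET.Element,
    x1: float,
    y1: float,
    x2: float,
    y2: float,
    width: float,
    dash: str | None,
    color: str,
    cls: str = "",
) -> ET.Element:
    el = ET.SubElement(
        parent,
        "line",
        {
            "x1": _fmt(x1),
            "y1": _fmt(y1),
            "x2": _fmt(x2),
            "y2": _fmt(y2),
            "stroke": color,
            "stroke-width": _fmt(width),
        },
    )
    if dash:
        el.set("stroke-dasharray", dash)
    if cls:
        el.set("class", cls)
    return el


def _text(
    parent: ET.Element, x: float, y: float, content: str, size: float, cls: str = "label", anchor: str = "middle"
) -> ET.Element:
    el = ET.SubElement(
        parent,
        "text",
        {
            "x": _fmt(x),
            "y": _fmt(y),
            "font-size": _fmt(size),
            "text-anchor": anchor,
            "font-family": "sans-serif",
            "class": cls,
        },
    )
    el.text = content
    return el


def _title(parent: ET.Element, popup: str) -> None:
    if popup:
        ET.SubElement(parent, "title").text = popup


def _svg_root(width: float, height: float, scale: AgeScale) -> ET.Element:
    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _fmt(width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )
    meta = ET.SubElement(root, "metadata")
    meta.text = json.dumps(
        {
            "age_scale": {
                "old": scale.old,
                "young": scale.young,
                "units_per_myr": scale.units_per_myr,
                "y_top": scale.y_top,
            }
        }
    )
    return root


def _axis(root: ET.Element, scale: AgeScale, settings: ChartSettings, x: float) -> None:
    group = ET.SubElement(root, "g", {"class": "age-axis"})
    _line(group, x, scale.y_top, x, scale.y_bottom, 1.0, None, "#000000", "axis-line")
    age = scale.young
    while age <= scale.old + 1e-9:
        y = scale.y(age)
        _line(group, x - 4, y, x, y, 1.0, None, "#000000", "axis-tick")
        _text(group, x - 6, y + 3, f"{age:g}", settings.font_size_phenon, "axis-label", "end")
        age += settings.tick_interval


def _background(root: ET.Element, scale: AgeScale, settings: ChartSettings, width: float) -> None:
    if not settings.background_bands:
        return
    group = ET.SubElement(root, "g", {"class": "background-bands"})
    for old, young, color, label in settings.background_bands:
        y_top, y_bot = scale.y(young), scale.y(old)
        rect = ET.SubElement(
            group,
            "rect",
            {
                "x": "0",
                "y": _fmt(y_top),
                "width": _fmt(width),
                "height": _fmt(y_bot - y_top),
                "fill": color,
                "class": "band",
            },
        )
        _title(rect, label)
        if label:
            _text(group, 4, (y_top + y_bot) / 2, label, settings.font_size_phenon, "band-label", "start")


def _side_runs(
    group: ET.Element,
    x: float,
    runs: list[tuple[float, float, str]],
    scale: AgeScale,
    styles: StyleSpec,
    default_token: str,
    color: str,
    side: str,
) -> None:
    for old, young, token in runs:
        tok = (token.strip().lower() or default_token)
        width, dash = styles.get(token, default_token)
        _line(
            group,
            x,
            scale.y(old),
            x,
            scale.y(young),
            width,
            dash,
            color,
            f"box-side side-{side} style-{tok if tok in styles.tokens else styles.fallback}",
        )


def _symbol(
    group: ET.Element,
    kind: TopSymbol | BaseSymbol,
    x: float,
    y: float,
    styles: StyleSpec,
    color: str,
) -> None:
    s = styles.symbol_size
    cls = f"symbol symbol-{kind.value}"
    if kind is BaseSymbol.RANGE_ORIGIN:
        _line(group, x - s, y, x + s, y, 1.5, None, color, cls)
    elif kind is TopSymbol.RANGE_TOP_EXTINCT:
        _line(group, x - s, y, x + s, y, 2.5, None, color, cls)
    elif kind is TopSymbol.RANGE_TOP_LIVING:
        ET.SubElement(
            group,
            "polygon",
            {
                "points": f"{_fmt(x - s)},{_fmt(y + s)} {_fmt(x)},{_fmt(y - s)} {_fmt(x + s)},{_fmt(y + s)}",
                "fill": color,
                "class": cls,
            },
        )
    elif kind is TopSymbol.BROKEN_TOP:
        ET.SubElement(
            group,
            "polyline",
            {
                "points": f"{_fmt(x - s)},{_fmt(y + s)} {_fmt(x)},{_fmt(y)} {_fmt(x + s)},{_fmt(y + s)}",
                "fill": "none",
                "stroke": color,
                "stroke-width": "1.5",
                "class": cls,
            },
        )
    elif kind is BaseSymbol.BROKEN_BASE:
        ET.SubElement(
            group,
            "polyline",
            {
                "points": f"{_fmt(x - s)},{_fmt(y - s)} {_fmt(x)},{_fmt(y)} {_fmt(x + s)},{_fmt(y - s)}",
                "fill": "none",
                "stroke": color,
                "stroke-width": "1.5",
                "class": cls,
            },
        )


def _segment_group(
    parent: ET.Element,
    seg: PhenonSegment,
    x: float,
    scale: AgeScale,
    settings: ChartSettings,
    styles: StyleSpec,
) -> None:
    color = seg.color or settings.default_color
    g = ET.SubElement(
        parent,
        "g",
        {"class": "phenon-segment", "id": f"seg-{_safe_id(seg.phenon_name)}-{_safe_id(seg.host_species)}"},
    )
    _title(g, seg.popup)
    runs = seg.style_runs or [(seg.old_age, seg.young_age, "")]
    for old, young, token in runs:
        tok = token.strip().lower() or settings.default_phenon_style
        width, dash = styles.get(token, settings.default_phenon_style)
        _line(
            g,
            x,
            scale.y(old),
            x,
            scale.y(young),
            width,
            dash,
            color,
            f"segment-run style-{tok if tok in styles.tokens else styles.fallback}",
        )
    _symbol(g, seg.base_symbol, x, scale.y(seg.old_age), styles, settings.accent_color)
    _symbol(g, seg.top_symbol, x, scale.y(seg.young_age), styles, settings.accent_color)
    if settings.show_labels:
        _text(
            g,
            x,
            scale.y(seg.young_age) - styles.symbol_size - 2,
            seg.display_label,
            settings.font_size_phenon,
            "phenon-label",
        )


def render(
    layout: Layout,
    rmap: RelationshipMap,
    settings: ChartSettings | None = None,
    styles: StyleSpec | None = None,
) -> str:
    """Render the integrated species-phenon chart to SVG text."""
    settings = settings or layout.settings
    styles = styles or StyleSpec()
    scale = layout.scale
    root = _svg_root(layout.width, layout.height, scale)
    _background(root, scale, settings, layout.width)
    _axis(root, scale, settings, settings.margin + settings.axis_width - 8)

    # species branch lines first layer above the boxes' fills, drawn after
    # boxes so they sit on top of the fills but under the symbols
    boxes_g = ET.SubElement(root, "g", {"class": "species-boxes"})
    for box in layout.boxes.values():
        color = box.color or settings.default_color
        g = ET.SubElement(boxes_g, "g", {"class": "species-box", "id": f"box-{_safe_id(box.species)}"})
        _title(g, box.popup)
        ET.SubElement(
            g,
            "rect",
            {
                "x": _fmt(box.x_left),
                "y": _fmt(box.y_top),
                "width": _fmt(box.width),
                "height": _fmt(box.y_bottom - box.y_top),
                "fill": color,
                "fill-opacity": _fmt(settings.box_alpha),
                "stroke": "none",
                "class": "box-fill",
            },
        )
        runs = box.style_runs or [(box.base_age, box.top_age, "")]
        _side_runs(g, box.x_left, runs, scale, styles, settings.default_species_style, color, "left")
        _side_runs(g, box.x_right, runs, scale, styles, settings.default_species_style, color, "right")
        base_token = runs[0][2]
        top_token = runs[-1][2]
        w, dash = styles.get(base_token, settings.default_species_style)
        _line(g, box.x_left, box.y_bottom, box.x_right, box.y_bottom, w, dash, color, "box-side side-base")
        w, dash = styles.get(top_token, settings.default_species_style)
        _line(g, box.x_left, box.y_top, box.x_right, box.y_top, w, dash, color, "box-side side-top")
        if box.still_living:
            _symbol(g, TopSymbol.RANGE_TOP_LIVING, box.x_center, box.y_top, styles, settings.accent_color)
        if settings.show_labels:
            _text(
                g,
                box.x_center,
                box.y_top - 6,
                box.species,
                settings.font_size_species,
                "species-label",
            )

    branches_g = ET.SubElement(root, "g", {"class": "species-branches"})
    for parent, child, age, x_from, x_to, color, style, visible in layout.species_branches:
        if not visible:
            continue
        dash = {"dashed": "5 3", "dotted": "1 3"}.get(style or "", None)
        w, _ = styles.get("", settings.default_species_style)
        el = _line(
            branches_g,
            x_from,
            scale.y(age),
            x_to,
            scale.y(age),
            w,
            dash,
            color or settings.default_color,
            "species-branch",
        )
        el.set("id", f"branch-{_safe_id(parent)}-{_safe_id(child)}")

    segs_g = ET.SubElement(root, "g", {"class": "phenon-segments"})
    for species in rmap.species_order:
        for seg in rmap.group(species):
            x = layout.segment_x[(seg.phenon_name, species)]
            _segment_group(segs_g, seg, x, scale, settings, styles)
    pb_g = ET.SubElement(root, "g", {"class": "phenon-branches"})
    for parent, child, host, age, x_from, x_to, color, style, visible in layout.phenon_branches:
        if not visible:
            continue
        dash = {"dashed": "5 3", "dotted": "1 3"}.get(style or "", None)
        w, _ = styles.get("", settings.default_phenon_style)
        _line(
            pb_g,
            x_from,
            scale.y(age),
            x_to,
            scale.y(age),
            w,
            dash,
            color or settings.default_color,
            "phenon-branch",
        )
    return ET.tostring(root, encoding="unicode")


def render_component_trees(
    tree: EvoTree,
    settings: ChartSettings = ChartSettings(),
    styles: StyleSpec | None = None,
    default_style: str | None = None,
) -> str:
    """Render a plain range-line tree (no boxes) for side-by-side
    comparison with the integrated chart: one vertical range line per
    taxon, one horizontal branch line per branch, one label per range."""
    from .tree_model import style_segments

    styles = styles or StyleSpec()
    default_token = default_style or (
        settings.default_phenon_style
        if any(r.is_phenon for r in tree.ranges.values())
        else settings.default_species_style
    )
    cl = position_component_tree(tree, settings)
    scale = cl.scale
    root = _svg_root(cl.width, cl.height, scale)
    _background(root, scale, settings, cl.width)
    _axis(root, scale, settings, settings.margin + settings.axis_width - 8)
    ranges_g = ET.SubElement(root, "g", {"class": "ranges"})
    for name, rng in tree.ranges.items():
        x = cl.range_x[name]
        g = ET.SubElement(ranges_g, "g", {"class": "range", "id": f"range-{_safe_id(name)}"})
        _title(g, rng.popup)
        runs = style_segments(rng) or [(rng.base_age, rng.top_age, "")]
        color = rng.color or settings.default_color
        for old, young, token in runs:
            width, dash = styles.get(token, default_token)
            _line(g, x, scale.y(old), x, scale.y(young), width, dash, color, "range-run")
        if rng.still_living:
            _symbol(g, TopSymbol.RANGE_TOP_LIVING, x, scale.y(rng.top_age), styles, settings.accent_color)
    branches_g = ET.SubElement(root, "g", {"class": "branches"})
    for parent, child, age, x_from, x_to, color, style, visible in cl.branches:
        if not visible:
            continue
        dash = {"dashed": "5 3", "dotted": "1 3"}.get(style or "", None)
        width, _ = styles.get("", default_token)
        _line(
            branches_g,
            x_from,
            scale.y(age),
            x_to,
            scale.y(age),
            width,
            dash,
            color or settings.default_color,
            "branch",
        )
    labels_g = ET.SubElement(root, "g", {"class": "labels"})
    for name, rng in tree.ranges.items():
        from .datapack_io import split_display_label

        _text(
            labels_g,
            cl.range_x[name],
            scale.y(rng.top_age) - 4,
            split_display_label(name)[0],
            settings.font_size_phenon,
            "range-label",
        )
    return ET.tostring(root, encoding="unicode")
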