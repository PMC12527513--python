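"""Render resolved layouts to static images or interactive HTML.

Renderers only map layout coordinates to pixels; no statistical quantity
is computed here. The interactive output is a single self-contained HTML
file: an SVG whose elements carry their hover text, a small tooltip
script, and the full layout serialized into a ``<script
type="application/json" id="marcplot-data">`` block so the numbers shown
can be recovered from the document itself.
"""

from __future__ import annotations

import dataclasses
import json
from html import escape
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .layouts import BarLayout, ForestLayout, MarcLayout

__all__ = ["render", "layout_to_dict", "DEFAULT_PALETTE"]

#: Diverging, colorblind-safe: red = decreased scores, blue = increased.
DEFAULT_PALETTE = {
    "negative": "#ca0020",
    "positive": "#0571b0",
    "zero": "#7f7f7f",
    "summary": "#404040",
}

Layout = Union[MarcLayout, ForestLayout, BarLayout]


def layout_to_dict(layout: Layout) -> dict:
    """Serialize a layout to plain JSON-ready data (exact float repr)."""

    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    d = conv(layout)
    d["kind"] = layout.kind
    return d


def render(layout: Layout, path, target: Optional[str] = None) -> Path:
    """Write ``layout`` to ``path``.

    ``target`` is ``"static"`` (PNG or SVG, chosen by the path suffix)
    or ``"interactive"`` (self-contained HTML); if omitted it is
    inferred from the suffix (.png/.svg -> static, .html -> interactive).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if target is None:
        target = "interactive" if suffix == ".html" else "static"
    if target == "static":
        if suffix not in (".png", ".svg"):
            raise ValueError(f"static rendering supports .png/.svg, got {suffix!r}")
        _render_static(layout, path)
    elif target == "interactive":
        if suffix != ".html":
            raise ValueError(f"interactive rendering writes .html, got {suffix!r}")
        _render_html(layout, path)
    else:
        raise ValueError(f"unsupported render target {target!r}")
    return path


# ---------------------------------------------------------------------------
# static (matplotlib)

def _x_limits(layout: Layout) -> tuple[float, float]:
    xs = [0.0, layout.pooled.ci_low, layout.pooled.ci_high]
    if isinstance(layout, MarcLayout):
        xs += [m.x for m in layout.marks] + list(layout.cloud.x)
    elif isinstance(layout, ForestLayout):
        for r in layout.rows:
            xs += [r.ci_low, r.ci_high]
    else:
        xs += [r.signed_end for r in layout.rows]
    lo, hi = min(xs), max(xs)
    pad = 0.08 * (hi - lo or 1.0)
    return lo - pad, hi + pad


def _direction_shading(ax, layout: Layout) -> None:
    lo, hi = ax.get_xlim()
    if lo < 0:
        ax.axvspan(lo, 0, color=DEFAULT_PALETTE["negative"], alpha=0.06, zorder=0)
    if hi > 0:
        ax.axvspan(0, hi, color=DEFAULT_PALETTE["positive"], alpha=0.06, zorder=0)
    ax.axvline(layout.zero_line, color="0.4", lw=0.8, zorder=1)


def _annotate_directions(ax, labels) -> None:
    neg, pos = labels
    ax.text(0.02, 1.02, neg, transform=ax.transAxes, ha="left",
            color=DEFAULT_PALETTE["negative"], fontsize=9)
    ax.text(0.98, 1.02, pos, transform=ax.transAxes, ha="right",
            color=DEFAULT_PALETTE["positive"], fontsize=9)


def _draw_cloud(ax, layout: MarcLayout, y_center: float, y_scale: float) -> None:
    cloud = layout.cloud
    ax.scatter(cloud.x, y_center + cloud.y_offset * y_scale, s=12,
               color=DEFAULT_PALETTE["summary"], zorder=4)


def _marc_study_axis(ax, layout: MarcLayout, pane) -> None:
    for m in layout.marks:
        ax.scatter([m.x], [m.y], s=m.area, color=DEFAULT_PALETTE[m.color],
                   alpha=0.75, zorder=3)
    ax.set_ylim(*pane.y_range)
    more, less = layout.annotations.certainty_arrows
    ax.set_ylabel(f"{less}  $\\leftarrow$  weight  $\\rightarrow$  {more}")


def _render_static_marc(layout: MarcLayout, path: Path) -> None:
    if layout.version == "v1":
        fig, ax = plt.subplots(figsize=(8, 5))
        pane = layout.panes[0]
        _marc_study_axis(ax, layout, pane)
        ax.set_xlim(*_x_limits(layout))
        _direction_shading(ax, layout)
        xspan = np.diff(ax.get_xlim())[0]
        _draw_cloud(ax, layout, layout.summary_y,
                    y_scale=np.diff(pane.y_range)[0] / xspan)
        _annotate_directions(ax, layout.annotations.direction_labels)
        ax.set_xlabel("Standardized mean difference")
        axes = [ax]
    else:
        fig, (ax_top, ax_bot) = plt.subplots(
            2, 1, figsize=(8, 6), sharex=True,
            gridspec_kw={"height_ratios": [p.height_ratio for p in layout.panes]},
        )
        ax_bot.set_xlim(*_x_limits(layout))
        xspan = np.diff(ax_bot.get_xlim())[0]
        top_pane, bot_pane = layout.panes
        ax_top.set_ylim(*top_pane.y_range)
        _direction_shading(ax_top, layout)
        _draw_cloud(ax_top, layout, layout.summary_y,
                    y_scale=np.diff(top_pane.y_range)[0] / xspan)
        ax_top.set_yticks([])
        ax_top.set_ylabel("Summary")
        _annotate_directions(ax_top, layout.annotations.direction_labels)
        _marc_study_axis(ax_bot, layout, bot_pane)
        _direction_shading(ax_bot, layout)
        ax_bot.set_xlabel("Standardized mean difference")
        axes = [ax_top, ax_bot]
    for a in axes:
        a.spines[["top", "right"]].set_visible(False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _render_static_forest(layout: ForestLayout, path: Path) -> None:
    n = layout.n_rows
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * n + 1)))
    ax.set_xlim(*_x_limits(layout))
    _direction_shading(ax, layout)
    for r in layout.rows:
        y = n - 1 - r.row
        ax.hlines(y, r.ci_low, r.ci_high, color="0.3", lw=1)
        ax.scatter([r.x], [y], s=r.area, marker="s",
                   color=DEFAULT_PALETTE[r.color], zorder=3)
    lo, est, hi = layout.diamond_x
    dy = n - 1 - layout.diamond_row
    ax.fill([lo, est, hi, est], [dy, dy + 0.3, dy, dy - 0.3],
            color=DEFAULT_PALETTE["summary"])
    ax.set_yticks([n - 1 - r.row for r in layout.rows] + [dy])
    ax.set_yticklabels([r.study_id for r in layout.rows] + ["Summary"], fontsize=7)
    ax.set_xlabel("Standardized mean difference")
    ax.spines[["top", "right"]].set_visible(False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _render_static_bar(layout: BarLayout, path: Path) -> None:
    n = layout.n_rows
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * n + 1)))
    for r in layout.rows:
        y = n - 1 - r.row
        color = DEFAULT_PALETTE["summary"] if r.is_summary else DEFAULT_PALETTE[r.color]
        ax.barh(y, r.signed_end, height=0.7, color=color, alpha=0.85)
    ax.set_xlim(*_x_limits(layout))
    _direction_shading(ax, layout)
    ax.set_yticks([n - 1 - r.row for r in layout.rows])
    ax.set_yticklabels([r.study_id for r in layout.rows], fontsize=7)
    ax.set_xlabel("Standardized mean difference")
    ax.spines[["top", "right"]].set_visible(False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _render_static(layout: Layout, path: Path) -> None:
    if isinstance(layout, MarcLayout):
        _render_static_marc(layout, path)
    elif isinstance(layout, ForestLayout):
        _render_static_forest(layout, path)
    elif isinstance(layout, BarLayout):
        _render_static_bar(layout, path)
    else:
        raise TypeError(f"cannot render {type(layout).__name__}")


# ---------------------------------------------------------------------------
# interactive (self-contained SVG + tooltip HTML)

_TOOLTIP_JS = """
(function () {
  var tip = document.getElementById('marcplot-tooltip');
  document.querySelectorAll('[data-hover]').forEach(function (el) {
    el.addEventListener('mousemove', function (ev) {
      tip.innerHTML = el.getAttribute('data-hover').split('\\n').join('<br>');
      tip.style.left = (ev.pageX + 12) + 'px';
      tip.style.top = (ev.pageY + 12) + 'px';
      tip.style.display = 'block';
    });
    el.addEventListener('mouseleave', function () {
      tip.style.display = 'none';
    });
  });
})();
"""

_CSS = """
body { font-family: sans-serif; }
#marcplot-tooltip { position: absolute; display: none; background: #fff;
  border: 1px solid #888; padding: 4px 6px; font-size: 12px;
  pointer-events: none; box-shadow: 1px 1px 3px rgba(0,0,0,.3); }
[data-hover] { cursor: pointer; }
"""


class _Scale:
    def __init__(self, lo, hi, px0, px1):
        self.lo, self.hi, self.px0, self.px1 = lo, hi, px0, px1

    def __call__(self, v):
        t = (v - self.lo) / (self.hi - self.lo)
        return self.px0 + t * (self.px1 - self.px0)


def _svg_marc(layout: MarcLayout, width: int, height: int) -> list[str]:
    margin = 50
    xlim = _x_limits(layout)
    sx = _Scale(xlim[0], xlim[1], margin, width - margin)
    px_per_x = (width - 2 * margin) / (xlim[1] - xlim[0])
    parts = []
    if layout.version == "v1":
        pane = layout.panes[0]
        sy = _Scale(pane.y_range[0], pane.y_range[1], height - margin, margin)
        cloud_cy = sy(layout.summary_y)
        study_sy = sy
    else:
        ratios = [p.height_ratio for p in layout.panes]
        inner = height - 2 * margin
        top_h = inner * ratios[0] / sum(ratios)
        top_pane, bot_pane = layout.panes
        sy_top = _Scale(top_pane.y_range[0], top_pane.y_range[1],
                        margin + top_h, margin)
        study_sy = _Scale(bot_pane.y_range[0], bot_pane.y_range[1],
                          height - margin, margin + top_h + 10)
        cloud_cy = sy_top(layout.summary_y)
        parts.append(
            f'<line x1="{margin}" y1="{margin + top_h + 5}" '
            f'x2="{width - margin}" y2="{margin + top_h + 5}" stroke="#ccc"/>'
        )
    zx = sx(layout.zero_line)
    parts.append(f'<line x1="{zx}" y1="{margin}" x2="{zx}" '
                 f'y2="{height - margin}" stroke="#999" stroke-dasharray="3,3"/>')
    neg, pos = layout.annotations.direction_labels
    parts.append(f'<text x="{margin}" y="{margin - 14}" '
                 f'fill="{DEFAULT_PALETTE["negative"]}" font-size="12">{escape(neg)}</text>')
    parts.append(f'<text x="{width - margin}" y="{margin - 14}" text-anchor="end" '
                 f'fill="{DEFAULT_PALETTE["positive"]}" font-size="12">{escape(pos)}</text>')
    more, less = layout.annotations.certainty_arrows
    parts.append(f'<text x="14" y="{height / 2}" font-size="11" '
                 f'transform="rotate(-90 14 {height / 2})" text-anchor="middle">'
                 f'{escape(less)} &#8592; weight &#8594; {escape(more)}</text>')
    for m in layout.marks:
        r = math_sqrt(m.area / 3.14159265) * 0.9
        parts.append(
            f'<circle cx="{sx(m.x)}" cy="{study_sy(m.y)}" r="{max(r, 2.0)}" '
            f'fill="{DEFAULT_PALETTE[m.color]}" fill-opacity="0.75" '
            f'data-hover="{escape_nl(m.hover)}"/>'
        )
    hover = (f"Summary\nSMD: {layout.pooled.estimate:.2f}\n"
             f"{int(layout.pooled.level * 100)}% CI: "
             f"[{layout.pooled.ci_low:.2f}, {layout.pooled.ci_high:.2f}]")
    for x, dy in layout.cloud.dots:
        parts.append(
            f'<circle cx="{sx(x)}" cy="{cloud_cy - dy * px_per_x}" r="3" '
            f'fill="{DEFAULT_PALETTE["summary"]}" data-hover="{escape(hover)}"/>'
        )
    return parts


def _svg_rows(layout, width: int, height: int) -> list[str]:
    margin = 50
    xlim = _x_limits(layout)
    sx = _Scale(xlim[0], xlim[1], margin, width - margin)
    n = layout.n_rows
    row_h = (height - 2 * margin) / n
    row_y = lambda row: margin + (row + 0.5) * row_h
    parts = []
    zx = sx(layout.zero_line)
    parts.append(f'<line x1="{zx}" y1="{margin}" x2="{zx}" '
                 f'y2="{height - margin}" stroke="#999" stroke-dasharray="3,3"/>')
    if isinstance(layout, ForestLayout):
        for r in layout.rows:
            y = row_y(r.row)
            side = max(math_sqrt(r.area) * 0.9, 3.0)
            parts.append(f'<line x1="{sx(r.ci_low)}" y1="{y}" '
                         f'x2="{sx(r.ci_high)}" y2="{y}" stroke="#444"/>')
            parts.append(
                f'<rect x="{sx(r.x) - side / 2}" y="{y - side / 2}" '
                f'width="{side}" height="{side}" fill="{DEFAULT_PALETTE[r.color]}" '
                f'data-hover="{escape_nl(r.hover)}"/>'
            )
        lo, est, hi = layout.diamond_x
        y = row_y(layout.diamond_row)
        h = row_h * 0.35
        pts = (f"{sx(lo)},{y} {sx(est)},{y - h} {sx(hi)},{y} {sx(est)},{y + h}")
        hover = f"Summary\nSMD: {est:.2f}"
        parts.append(f'<polygon points="{pts}" fill="{DEFAULT_PALETTE["summary"]}" '
                     f'data-hover="{escape(hover)}"/>')
    else:
        for r in layout.rows:
            y = row_y(r.row)
            color = DEFAULT_PALETTE["summary"] if r.is_summary else DEFAULT_PALETTE[r.color]
            x0, x1 = sorted((sx(0.0), sx(r.signed_end)))
            parts.append(
                f'<rect x="{x0}" y="{y - row_h * 0.35}" width="{max(x1 - x0, 0.5)}" '
                f'height="{row_h * 0.7}" fill="{color}" fill-opacity="0.85" '
                f'data-hover="{escape_nl(r.hover)}"/>'
            )
    return parts


def math_sqrt(v: float) -> float:
    return float(np.sqrt(v))


def escape_nl(lines) -> str:
    return escape("\n".join(lines))


def _render_html(layout: Layout, path: Path) -> None:
    if isinstance(layout, MarcLayout):
        width, height = 800, 520
        body = _svg_marc(layout, width, height)
    else:
        width = 800
        height = int(100 + 24 * layout.n_rows)
        body = _svg_rows(layout, width, height)
    data = json.dumps(layout_to_dict(layout))
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>marcplot {layout.kind}</title>
<style>{_CSS}</style></head>
<body>
<svg width="{width}" height="{height}" xmlns="http://www.w3.org/2000/svg">
{''.join(body)}
</svg>
<div id="marcplot-tooltip"></div>
<script type="application/json" id="marcplot-data">{data}</script>
<script>{_TOOLTIP_JS}</script>
</body></html>
"""
    path.write_text(html, encoding="utf-8")
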