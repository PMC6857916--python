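"""Deterministic SVG rendering of a nomogram layout.

Hand-built SVG 1.1 (plain string assembly, fixed number formatting) so
that identical layouts render to byte-identical documents — a property
the golden-file tests rely on.
"""

from __future__ import annotations

import json

from .layout import AxisSpec, NomogramLayout

__all__ = ["render_svg", "layout_to_dict"]

_MARGIN_L = 150.0
_MARGIN_R = 40.0
_ROW_H = 52.0
_TICK_H = 6.0
_WIDTH = 820.0


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def _ruler(out: list[str], y: float, label: str,
           ticks: list[tuple[str, float]], x_of, cls: str) -> None:
    out.append(
        f'<text x="{_fmt(_MARGIN_L - 10)}" y="{_fmt(y + 4)}" text-anchor="end" '
        f'class="axis-label">{_esc(label)}</text>'
    )
    if ticks:
        lo = min(p for _, p in ticks)
        hi = max(p for _, p in ticks)
        out.append(
            f'<line x1="{_fmt(x_of(lo))}" y1="{_fmt(y)}" x2="{_fmt(x_of(hi))}" '
            f'y2="{_fmt(y)}" class="{cls}"/>'
        )
    for text, pts in ticks:
        x = x_of(pts)
        out.append(
            f'<line x1="{_fmt(x)}" y1="{_fmt(y - _TICK_H)}" x2="{_fmt(x)}" '
            f'y2="{_fmt(y)}" class="{cls}"/>'
        )
        out.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y - _TICK_H - 3)}" '
            f'text-anchor="middle" class="tick-label">{_esc(text)}</text>'
        )


def _esc(s: str) -> str:
    return (
        str(s)
        .replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_svg(layout: NomogramLayout, options: dict | None = None) -> str:
    """Render a :class:`NomogramLayout` to an SVG 1.1 document string.

    One horizontal ruler per axis under a shared 0–100 points scale, with
    the total-points and response rulers at the bottom.  Output is
    byte-identical for identical inputs.
    """
    options = dict(options or {})
    title = options.get("title", "Nomogram")
    n_axes = len(layout.axes)
    height = _ROW_H * (n_axes + 3) + 60.0
    plot_w = _WIDTH - _MARGIN_L - _MARGIN_R

    def x_points(p: float) -> float:  # 0..100 points scale
        return _MARGIN_L + plot_w * p / 100.0

    t_lo, t_hi = layout.total_points_range
    t_span = (t_hi - t_lo) or 1.0

    def x_total(p: float) -> float:
        return _MARGIN_L + plot_w * (p - t_lo) / t_span

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(_WIDTH)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(_WIDTH)} {_fmt(height)}">',
        "<style>"
        "line.axis{stroke:#000;stroke-width:1}"
        "line.total{stroke:#444;stroke-width:1}"
        "text{font-family:Helvetica,Arial,sans-serif;font-size:10px;fill:#000}"
        "text.axis-label{font-size:11px}"
        "text.title{font-size:14px;font-weight:bold}"
        "</style>",
        f'<text x="{_fmt(_WIDTH / 2)}" y="20" text-anchor="middle" '
        f'class="title">{_esc(title)}</text>',
    ]

    y = 50.0
    points_ticks = [(_fmt(float(v)), float(v)) for v in range(0, 101, 10)]
    _ruler(out, y, "Points", points_ticks, x_points, "axis")
    for ax in layout.axes:
        y += _ROW_H
        label = ax.variable or "+".join(ax.term_names)
        if ax.stratum:
            label = f"{label} | {ax.stratum}"
        _ruler(out, y, label, [(t, p) for t, p in ax.ticks], x_points, "axis")

    y += _ROW_H + 10.0
    n_tt = 11
    tt = [t_lo + i * (t_hi - t_lo) / (n_tt - 1) for i in range(n_tt)]
    _ruler(out, y, "Total points", [(_fmt(v), v) for v in tt], x_total, "total")
    y += _ROW_H
    _ruler(
        out,
        y,
        layout.response_label,
        [(_fmt(r), p) for p, r in layout.response_ticks],
        x_total,
        "total",
    )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def layout_to_dict(layout: NomogramLayout) -> dict:
    """JSON-serializable form of the layout (documented schema)."""
    return {
        "format": "dynomo-layout",
        "version": 1,
        "points_per_unit_eta": layout.points_per_unit_eta,
        "total_points_range": list(layout.total_points_range),
        "eta_at_zero_points": layout.eta_at_zero_points,
        "response_label": layout.response_label,
        "response_ticks": [[p, r] for p, r in layout.response_ticks],
        "axes": [
            {
                "terms": list(ax.term_names),
                "variable": ax.variable,
                "stratum": ax.stratum,
                "ticks": [[t, p] for t, p in ax.ticks],
                "contribution_fn_grid": (
                    [[x, p] for x, p in ax.contribution_fn_grid]
                    if ax.contribution_fn_grid
                    else None
                ),
            }
            for ax in layout.axes
        ],
    }
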