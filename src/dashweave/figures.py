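"""Declarative figure specifications and a deterministic SVG renderer.

A :class:`FigureSpec` is the one documented figure form accepted by content
dispatch: a list of traces plus axis/encoding metadata. Supported trace kinds
are ``scatter``, ``bar``, ``box``, ``violin`` and ``heatmap``. Figures are
rendered server-side to self-contained inline SVG; rendering is a pure
function of the spec and the document colormaps (fixed float formatting, no
timestamps, no randomness), so repeated builds are byte-identical.

Rendered elements carry data attributes (``data-i`` on scatter points,
``data-level`` on bars) that the embedded linked-view script uses to update
targets after a selection; see :mod:`dashweave.linking`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import DispatchError

__all__ = ["Trace", "FigureSpec", "render_figure", "DEFAULT_PALETTE", "resolve_colors"]

TRACE_KINDS = ("scatter", "bar", "box", "violin", "heatmap")

#: Fallback categorical palette, assigned to sorted levels when no document
#: colormap is declared. Fixed so output is stable across runs.
DEFAULT_PALETTE = (
    "#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
    "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd",
)

# Sequential ramp stops for numeric color encodings (light -> dark).
_RAMP_STOPS = ("#f7fbff", "#c6dbef", "#6baed6", "#2171b5", "#08306b")


@dataclass
class Trace:
    """One data series of a figure.

    Parameters
    ----------
    kind:
        One of ``scatter``, ``bar``, ``box``, ``violin``, ``heatmap``.
    x, y:
        Coordinates. scatter: numeric/numeric. bar: category labels / heights.
        box and violin: category labels (one per observation) / numeric values.
        heatmap: column labels / row labels, with the matrix in ``z``.
    z:
        Heatmap matrix, rows x columns, row i matching ``y[i]``.
    color_by:
        Optional per-point encoding for scatter: categorical levels or
        numeric values (continuous ramp).
    name:
        Series label, used for tab/legend text.
    """

    kind: str
    x: Sequence[Any] = field(default_factory=list)
    y: Sequence[Any] = field(default_factory=list)
    z: Sequence[Sequence[float]] | None = None
    color_by: Sequence[Any] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRACE_KINDS:
            raise DispatchError(
                f"unknown trace kind {self.kind!r}; valid kinds: "
                + ", ".join(TRACE_KINDS)
            )


@dataclass
class FigureSpec:
    """Declarative figure: traces plus axis and encoding metadata.

    ``colormap`` names a document-wide colormap used to color categorical
    encodings; ``category_var`` and ``value_var`` name the variables a linked
    view aggregates over (they refer to keys of the owning component's data
    payload and are carried into the compiled wiring).
    """

    traces: list[Trace]
    title: str = ""
    xlabel: str = ""
    ylabel: str = ""
    colormap: str | None = None
    category_var: str | None = None
    value_var: str | None = None
    #: Optional records attached to the figure's component as its data
    #: payload, the subset linked views select from and aggregate over.
    data: list[dict] | None = None

    def to_dict(self) -> dict:
        """Spec as plain JSON-ready data (the ``data`` records are carried on
        the fragment's payload instead and are not duplicated here)."""
        def conv(v):
            if isinstance(v, np.generic):
                return v.item()
            return v

        return {
            "title": self.title,
            "xlabel": self.xlabel,
            "ylabel": self.ylabel,
            "colormap": self.colormap,
            "category_var": self.category_var,
            "value_var": self.value_var,
            "traces": [
                {
                    "kind": t.kind,
                    "x": [conv(v) for v in t.x],
                    "y": [conv(v) for v in t.y],
                    "z": None if t.z is None else [[float(v) for v in row] for row in t.z],
                    "color_by": None if t.color_by is None else [conv(v) for v in t.color_by],
                    "name": t.name,
                }
                for t in self.traces
            ],
        }


def _f(v: float) -> str:
    """Fixed-precision coordinate formatting (determinism)."""
    s = f"{float(v):.2f}"
    return "0.00" if s == "-0.00" else s


def _esc(s: Any) -> str:
    return (
        str(s)
        .replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    return int(h[1:3], 16), int(h[3:5], 16), int(h[5:7], 16)


def _ramp(t: float) -> str:
    """Interpolate the sequential ramp at t in [0, 1]."""
    t = min(max(float(t), 0.0), 1.0)
    pos = t * (len(_RAMP_STOPS) - 1)
    i = min(int(pos), len(_RAMP_STOPS) - 2)
    frac = pos - i
    a, b = _hex_to_rgb(_RAMP_STOPS[i]), _hex_to_rgb(_RAMP_STOPS[i + 1])
    rgb = tuple(round(a[k] + (b[k] - a[k]) * frac) for k in range(3))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def resolve_colors(levels: Sequence[Any], colormap: dict[str, str] | None) -> dict[Any, str]:
    """Map category levels to hex colors.

    Levels present in the (document-wide) colormap use its assignment; the
    remainder take palette colors in sorted-level order. The same (colormap,
    level) pair therefore resolves identically everywhere in a document.
    """
    colormap = colormap or {}
    out: dict[Any, str] = {}
    uncovered = [lv for lv in sorted(set(map(str, levels))) if lv not in colormap]
    for lv in sorted(set(map(str, levels))):
        if lv in colormap:
            out[lv] = colormap[lv]
        else:
            out[lv] = DEFAULT_PALETTE[uncovered.index(lv) % len(DEFAULT_PALETTE)]
    return out


def _ticks(lo: float, hi: float, n: int = 5) -> list[float]:
    """Round tick locations covering [lo, hi] (1/2/5 progression)."""
    if not math.isfinite(lo) or not math.isfinite(hi):
        return [0.0]
    if hi <= lo:
        hi = lo + 1.0
    raw = (hi - lo) / max(n, 1)
    mag = 10.0 ** math.floor(math.log10(raw))
    for m in (1.0, 2.0, 5.0, 10.0):
        step = m * mag
        if raw <= step:
            break
    start = math.ceil(lo / step) * step
    ticks, v, i = [], start, 0
    while v <= hi + 1e-9 and i < 20:
        ticks.append(round(v, 10))
        i += 1
        v = start + i * step
    return ticks or [lo]


class _Canvas:
    """Accumulates SVG elements inside a margin-framed plot area."""

    def __init__(self, width: int, height: int, title: str, xlabel: str, ylabel: str):
        self.w, self.h = width, height
        self.ml, self.mr = 58, 14
        self.mt = 30 if title else 16
        self.mb = 42
        self.title, self.xlabel, self.ylabel = title, xlabel, ylabel
        self.parts: list[str] = []

    @property
    def pw(self) -> float:
        return self.w - self.ml - self.mr

    @property
    def ph(self) -> float:
        return self.h - self.mt - self.mb

    def sx(self, v: float, lo: float, hi: float) -> float:
        span = hi - lo or 1.0
        return self.ml + (v - lo) / span * self.pw

    def sy(self, v: float, lo: float, hi: float) -> float:
        span = hi - lo or 1.0
        return self.mt + self.ph - (v - lo) / span * self.ph

    def axes(self, xlo, xhi, ylo, yhi, x_categories=None):
        p = self.parts
        p.append(
            f'<rect x="{_f(self.ml)}" y="{_f(self.mt)}" width="{_f(self.pw)}" '
            f'height="{_f(self.ph)}" class="dw-plotbg"/>'
        )
        if x_categories is None:
            for t in _ticks(xlo, xhi):
                x = self.sx(t, xlo, xhi)
                p.append(f'<line x1="{_f(x)}" y1="{_f(self.mt + self.ph)}" x2="{_f(x)}" y2="{_f(self.mt + self.ph + 4)}" class="dw-tick"/>')
                p.append(f'<text x="{_f(x)}" y="{_f(self.mt + self.ph + 16)}" class="dw-ticklab" text-anchor="middle">{_esc(f"{t:g}")}</text>')
        else:
            n = len(x_categories)
            for i, lab in enumerate(x_categories):
                x = self.ml + (i + 0.5) / max(n, 1) * self.pw
                p.append(f'<text x="{_f(x)}" y="{_f(self.mt + self.ph + 16)}" class="dw-ticklab" text-anchor="middle">{_esc(lab)}</text>')
        for t in _ticks(ylo, yhi):
            y = self.sy(t, ylo, yhi)
            p.append(f'<line x1="{_f(self.ml - 4)}" y1="{_f(y)}" x2="{_f(self.ml)}" y2="{_f(y)}" class="dw-tick"/>')
            p.append(f'<text x="{_f(self.ml - 7)}" y="{_f(y + 3.5)}" class="dw-ticklab" text-anchor="end">{_esc(f"{t:g}")}</text>')
        if self.xlabel:
            p.append(f'<text x="{_f(self.ml + self.pw / 2)}" y="{_f(self.h - 8)}" class="dw-axlab" text-anchor="middle">{_esc(self.xlabel)}</text>')
        if self.ylabel:
            cx, cy = 14, self.mt + self.ph / 2
            p.append(f'<text x="{_f(cx)}" y="{_f(cy)}" class="dw-axlab" text-anchor="middle" transform="rotate(-90 {_f(cx)} {_f(cy)})">{_esc(self.ylabel)}</text>')

    def finish(self, element_id: str, kind: str) -> str:
        head = (
            f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {self.w} {self.h}" '
            f'class="dw-fig" id="{_esc(element_id)}-svg" data-kind="{_esc(kind)}" '
            f'width="100%" preserveAspectRatio="xMidYMid meet">'
        )
        title = (
            f'<text x="{_f(self.w / 2)}" y="16" class="dw-title" text-anchor="middle">{_esc(self.title)}</text>'
            if self.title
            else ""
        )
        return head + title + "".join(self.parts) + "</svg>"


def _num(seq) -> np.ndarray:
    return np.asarray(list(seq), dtype=float)


def _pad(lo: float, hi: float) -> tuple[float, float]:
    if hi <= lo:
        return lo - 0.5, hi + 0.5
    pad = (hi - lo) * 0.05
    return lo - pad, hi + pad


def _render_scatter(c: _Canvas, traces, colormap) -> None:
    xs = np.concatenate([_num(t.x) for t in traces])
    ys = np.concatenate([_num(t.y) for t in traces])
    xlo, xhi = _pad(float(np.min(xs)), float(np.max(xs)))
    ylo, yhi = _pad(float(np.min(ys)), float(np.max(ys)))
    c.axes(xlo, xhi, ylo, yhi)
    idx = 0
    for t in traces:
        x, y = _num(t.x), _num(t.y)
        if t.color_by is not None:
            cb = list(t.color_by)
            numeric = all(isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool) for v in cb)
            if numeric:
                vals = _num(cb)
                vlo, vhi = float(np.min(vals)), float(np.max(vals))
                span = vhi - vlo or 1.0
                colors = [_ramp((v - vlo) / span) for v in vals]
            else:
                lut = resolve_colors(cb, colormap)
                colors = [lut[str(v)] for v in cb]
        else:
            colors = [DEFAULT_PALETTE[0]] * len(x)
        for j in range(len(x)):
            c.parts.append(
                f'<circle cx="{_f(c.sx(x[j], xlo, xhi))}" cy="{_f(c.sy(y[j], ylo, yhi))}" '
                f'r="2.6" fill="{colors[j]}" fill-opacity="0.8" class="dw-pt" data-i="{idx}"/>'
            )
            idx += 1


def _render_bar(c: _Canvas, traces, colormap) -> None:
    t = traces[0]
    cats = [str(v) for v in t.x]
    vals = _num(t.y)
    ymax = float(np.max(vals)) if len(vals) and np.max(vals) > 0 else 1.0
    ylo, yhi = 0.0, ymax * 1.1
    c.axes(0, 1, ylo, yhi, x_categories=cats)
    lut = resolve_colors(cats, colormap)
    n = max(len(cats), 1)
    bw = c.pw / n * 0.7
    for i, (lab, v) in enumerate(zip(cats, vals)):
        xc = c.ml + (i + 0.5) / n * c.pw
        y = c.sy(v, ylo, yhi)
        c.parts.append(
            f'<rect x="{_f(xc - bw / 2)}" y="{_f(y)}" width="{_f(bw)}" '
            f'height="{_f(c.mt + c.ph - y)}" fill="{lut[lab]}" class="dw-bar" '
            f'data-level="{_esc(lab)}" data-x0="{_f(xc - bw / 2)}" data-bw="{_f(bw)}"/>'
        )
        c.parts.append(
            f'<text x="{_f(xc)}" y="{_f(y - 3)}" class="dw-barlab" text-anchor="middle" '
            f'data-level-label="{_esc(lab)}">{_esc(f"{v:g}")}</text>'
        )


def _quartiles(v: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = (float(x) for x in np.percentile(v, [25, 50, 75]))
    iqr = q3 - q1
    lo = float(np.min(v[v >= q1 - 1.5 * iqr])) if len(v) else 0.0
    hi = float(np.max(v[v <= q3 + 1.5 * iqr])) if len(v) else 0.0
    return lo, q1, med, q3, hi


def _grouped(t: Trace) -> tuple[list[str], dict[str, np.ndarray]]:
    labels = [str(v) for v in t.x]
    vals = _num(t.y)
    levels = sorted(set(labels))
    return levels, {lv: vals[np.array(labels) == lv] for lv in levels}


def _render_box(c: _Canvas, traces, colormap, violin: bool) -> None:
    t = traces[0]
    levels, groups = _grouped(t)
    allv = _num(t.y)
    ylo, yhi = _pad(float(np.min(allv)), float(np.max(allv)))
    c.axes(0, 1, ylo, yhi, x_categories=levels)
    lut = resolve_colors(levels, colormap)
    n = len(levels)
    half = c.pw / n * 0.33
    for i, lv in enumerate(levels):
        v = groups[lv]
        xc = c.ml + (i + 0.5) / n * c.pw
        color = lut[lv]
        if violin and len(v) >= 3 and len(np.unique(v)) >= 2:
            from scipy.stats import gaussian_kde

            grid = np.linspace(float(np.min(v)), float(np.max(v)), 40)
            try:
                dens = gaussian_kde(v)(grid)
            except Exception:
                dens = np.ones_like(grid)
            dens = dens / (np.max(dens) or 1.0) * half
            right = [(xc + d, c.sy(g, ylo, yhi)) for g, d in zip(grid, dens)]
            left = [(xc - d, c.sy(g, ylo, yhi)) for g, d in zip(grid[::-1], dens[::-1])]
            pts = " ".join(f"{_f(px)},{_f(py)}" for px, py in right + left)
            c.parts.append(
                f'<polygon points="{pts}" fill="{color}" fill-opacity="0.55" '
                f'stroke="{color}" class="dw-violin" data-level="{_esc(lv)}"/>'
            )
            med = float(np.median(v))
            c.parts.append(
                f'<line x1="{_f(xc - half * 0.5)}" y1="{_f(c.sy(med, ylo, yhi))}" '
                f'x2="{_f(xc + half * 0.5)}" y2="{_f(c.sy(med, ylo, yhi))}" class="dw-median"/>'
            )
        else:
            lo, q1, med, q3, hi = _quartiles(v) if len(v) else (0, 0, 0, 0, 0)
            ylo_, yq1, ymed, yq3, yhi_ = (c.sy(u, ylo, yhi) for u in (lo, q1, med, q3, hi))
            c.parts.append(f'<line x1="{_f(xc)}" y1="{_f(ylo_)}" x2="{_f(xc)}" y2="{_f(yhi_)}" class="dw-whisker"/>')
            c.parts.append(
                f'<rect x="{_f(xc - half)}" y="{_f(yq3)}" width="{_f(2 * half)}" '
                f'height="{_f(yq1 - yq3)}" fill="{color}" fill-opacity="0.6" stroke="{color}" '
                f'class="dw-box" data-level="{_esc(lv)}"/>'
            )
            c.parts.append(f'<line x1="{_f(xc - half)}" y1="{_f(ymed)}" x2="{_f(xc + half)}" y2="{_f(ymed)}" class="dw-median"/>')


def _render_heatmap(c: _Canvas, traces) -> None:
    t = traces[0]
    z = np.asarray(t.z, dtype=float)
    cols = [str(v) for v in t.x]
    rows = [str(v) for v in t.y]
    nr, nc = z.shape
    zlo, zhi = float(np.min(z)), float(np.max(z))
    span = zhi - zlo or 1.0
    cw, ch = c.pw / max(nc, 1), c.ph / max(nr, 1)
    for i in range(nr):
        for j in range(nc):
            val = z[i, j]
            c.parts.append(
                f'<rect x="{_f(c.ml + j * cw)}" y="{_f(c.mt + i * ch)}" width="{_f(cw)}" '
                f'height="{_f(ch)}" fill="{_ramp((val - zlo) / span)}" class="dw-cell" '
                f'data-row="{_esc(rows[i])}" data-col="{_esc(cols[j])}">'
                f"<title>{_esc(rows[i])} / {_esc(cols[j])}: {val:.3g}</title></rect>"
            )
    for j, lab in enumerate(cols):
        c.parts.append(
            f'<text x="{_f(c.ml + (j + 0.5) * cw)}" y="{_f(c.mt + c.ph + 16)}" '
            f'class="dw-ticklab" text-anchor="middle">{_esc(lab)}</text>'
        )
    step = max(1, nr // 20)
    for i in range(0, nr, step):
        c.parts.append(
            f'<text x="{_f(c.ml - 5)}" y="{_f(c.mt + (i + 0.5) * ch + 3)}" '
            f'class="dw-ticklab" text-anchor="end">{_esc(rows[i])}</text>'
        )


def render_figure(
    spec: FigureSpec,
    element_id: str,
    colormaps: dict[str, dict[str, str]] | None = None,
    width: int = 640,
    height: int = 420,
) -> str:
    """Render *spec* to an inline SVG string.

    Pure for a fixed (spec, colormaps): two calls produce identical bytes.
    """
    if not spec.traces:
        raise DispatchError("figure specification has no traces")
    colormap = (colormaps or {}).get(spec.colormap or "", None)
    kind = spec.traces[0].kind
    c = _Canvas(width, height, spec.title, spec.xlabel, spec.ylabel)
    if kind == "scatter":
        _render_scatter(c, spec.traces, colormap)
    elif kind == "bar":
        _render_bar(c, spec.traces, colormap)
    elif kind in ("box", "violin"):
        _render_box(c, spec.traces, colormap, violin=(kind == "violin"))
    elif kind == "heatmap":
        _render_heatmap(c, spec.traces)
    else:  # pragma: no cover - Trace.__post_init__ already rejects this
        raise DispatchError(f"unknown trace kind {kind!r}")
    return c.finish(element_id, kind)
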