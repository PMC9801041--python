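"""Rendering: intermediate document -> self-contained single-file HTML.

The output embeds everything -- stylesheet, runtime script, images (base64
data URIs), figure SVGs, data and wiring JSON islands -- so the file can be
archived or mailed and opened offline in any browser. Rendering is
deterministic: no timestamps are emitted by default (pass
``build_info=True`` for an explicit build-info footer) and all content
derives from the intermediate document alone. :func:`external_references`
machine-checks self-containment.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from jinja2 import Environment
from markdown_it import MarkdownIt

from ._static import BASE_CSS, RUNTIME_JS
from .assemble import IntermediateDocument, PageSection
from .dispatch import ComponentFragment
from .figures import render_figure

__all__ = ["render_html", "external_references"]

_md = MarkdownIt("commonmark").enable("table")

_TEMPLATE = Environment(autoescape=False).from_string(
    """<!DOCTYPE html>
<html lang="en" data-theme="{{ theme }}">
<head>
<meta charset="utf-8">
<meta name="viewport" content="width=device-width, initial-scale=1">
<title>{{ title }}</title>
<style>{{ css }}</style>
</head>
<body>
<nav class="dw-nav">
<span class="dw-brand">{{ title }}</span>
{{ nav_html }}
{% if author %}<span class="dw-author">{{ author }}</span>{% endif %}
</nav>
<main>
{% if sidebar_global %}<div class="dw-page-body"><aside class="dw-sidebar">{{ sidebar_global }}</aside><div class="dw-slots">{% endif %}
{{ pages_html }}
{% if sidebar_global %}</div></div>{% endif %}
</main>
{% if footer %}<footer class="dw-footer">{{ footer }}</footer>{% endif %}
<script>{{ js }}</script>
</body>
</html>
"""
)


def _esc(s: str) -> str:
    return (
        str(s).replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


def _json_island(kind_class: str, ident: str, obj, attr: str = "id") -> str:
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=True)
    payload = payload.replace("</", "<\\/")  # keep </script> out of the island
    return f'<script type="application/json" class="{kind_class}" {attr}="{ident}">{payload}</script>'


def _fragment_html(frag: ComponentFragment, colormaps: dict) -> tuple[str, int]:
    """Render one component to HTML; returns (html, embedded asset count)."""
    parts = [f'<div class="dw-component" id="{_esc(frag.element_id)}">']
    if frag.title:
        parts.append(f"<h3>{_esc(frag.title)}</h3>")
    n_assets = 0
    downloads: list = []
    if frag.kind == "figure" and frag.figure is not None:
        parts.append(render_figure(frag.figure, frag.element_id, colormaps))
        downloads = list(frag.assets)
    else:
        body_html = _md.render(frag.body)
        for asset in frag.assets:
            # assets referenced from the body are embedded in place; the
            # rest (e.g. a CSV of plotted values) become download links
            if f"asset:{asset.asset_id}" in frag.body:
                uri = f"data:{asset.media_type};base64,{asset.payload_b64}"
                body_html = body_html.replace(f"asset:{asset.asset_id}", uri)
                n_assets += 1
            else:
                downloads.append(asset)
        if frag.kind == "table":
            body_html = body_html.replace("<table>", f'<table id="{_esc(frag.element_id)}-table">', 1)
        parts.append(body_html)
    for asset in downloads:
        uri = f"data:{asset.media_type};base64,{asset.payload_b64}"
        parts.append(
            f'<p class="dw-download"><a download="{_esc(asset.asset_id)}" '
            f'href="{uri}">download {_esc(asset.asset_id)}</a></p>'
        )
        n_assets += 1
    if frag.data_payload is not None:
        parts.append(_json_island("dw-data", f"data-{frag.element_id}", frag.data_payload))
    parts.append("</div>")
    return "".join(parts), n_assets


def _section_html(sec: PageSection, colormaps: dict) -> tuple[str, int]:
    frag_html: dict[str, str] = {}
    n_assets = 0
    for frag in sec.fragments:
        html, n = _fragment_html(frag, colormaps)
        frag_html[frag.element_id] = html
        n_assets += n

    slots = sec.slot_plan.slots
    if sec.layout == "focal_left":
        focal = [s for s in slots if s.name == "focal"]
        side = [s for s in slots if s.name.startswith("side_")]
        inner = '<div class="dw-layout-focal_left">'
        if focal:
            inner += f'<div class="dw-col-focal">{frag_html[focal[0].element_id]}</div>'
        if side:
            inner += '<div class="dw-col-side">' + "".join(
                frag_html[s.element_id] for s in side
            ) + "</div>"
        inner += "</div>"
    elif sec.layout == "grid_2x2":
        cells = []
        for s in slots:
            cells.append(frag_html[s.element_id] if s.element_id else '<div class="dw-component dw-empty"></div>')
        inner = '<div class="dw-layout-grid_2x2">' + "".join(cells) + "</div>"
    elif sec.layout == "tabset":
        labels = []
        panes = []
        for i, s in enumerate(slots):
            frag = sec.fragments[i]
            labels.append(
                f'<button class="{"active" if i == 0 else ""}">{_esc(frag.title or f"Tab {i + 1}")}</button>'
            )
            panes.append(
                f'<div class="dw-tabpane {"active" if i == 0 else ""}">{frag_html[s.element_id]}</div>'
            )
        inner = f'<div class="dw-tabbar">{"".join(labels)}</div>' + "".join(panes)
    else:  # storyboard
        inner = '<div class="dw-layout-storyboard">' + "".join(
            frag_html[s.element_id] for s in slots
        ) + "</div>"

    sidebar = ""
    if sec.sidebar is not None:
        sidebar = '<aside class="dw-sidebar">' + "".join(
            _md.render(f.body) for f in sec.sidebar.fragments
        ) + "</aside>"
    body = f'<div class="dw-page-body">{sidebar}<div class="dw-slots">{inner}</div></div>'
    wiring = ""
    if sec.wiring:
        wiring = _json_island(
            "dw-wiring", sec.page_id, [w.to_dict() for w in sec.wiring], attr="data-page"
        )
    return (
        f'<section class="dw-page" id="page-{_esc(sec.page_id)}">'
        f"<h2>{_esc(sec.title)}</h2>{body}{wiring}</section>"
    ), n_assets


def _nav_html(doc: IntermediateDocument) -> str:
    """Page links grouped by menu label, then explicit navbar items."""
    groups: dict[str | None, list[PageSection]] = {}
    for sec in doc.sections:
        groups.setdefault(sec.menu, []).append(sec)
    parts = []
    for menu, secs in groups.items():
        links = "".join(
            f'<a data-page="{_esc(s.page_id)}" href="#page-{_esc(s.page_id)}">{_esc(s.title)}</a>'
            for s in secs
        )
        if menu is None:
            parts.append(links)
        else:
            parts.append(
                f'<details><summary>{_esc(menu)} &#9662;</summary><div class="dw-menu">{links}</div></details>'
            )
    for label, ref in doc.navbar_items:
        if "://" in ref or ref.startswith("#"):
            parts.append(f'<a href="{_esc(ref)}">{_esc(label)}</a>')
        else:
            parts.append(f'<a data-page="{_esc(ref)}" href="#page-{_esc(ref)}">{_esc(label)}</a>')
    return "".join(parts)


def render_html(
    doc: IntermediateDocument,
    out_path: str | Path,
    build_info: bool = False,
) -> dict:
    """Render *doc* to a single self-contained HTML file.

    Returns a summary ``{"bytes_written", "page_count", "asset_count"}``.
    When the document's front matter declares ``interactive: true``, the same
    static HTML is emitted together with a served-mode stub note (full
    reactive serving is a documented stub; see the ``dashweave serve``
    command).
    """
    front = dict(doc.front_matter)
    pages_html = []
    n_assets = 0
    for sec in doc.sections:
        html, n = _section_html(sec, doc.colormaps)
        pages_html.append(html)
        n_assets += n
    sidebar_global = ""
    if doc.sidebar_global is not None:
        sidebar_global = "".join(_md.render(f.body) for f in doc.sidebar_global.fragments)

    footer = ""
    if front.get("interactive") == "true":
        footer = (
            "Rendered in static mode; the served interactive mode is a stub "
            "(run <code>dashweave serve</code> for details)."
        )
    if build_info:
        import datetime

        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
        footer += f" Built {stamp}."

    html = _TEMPLATE.render(
        title=_esc(front.get("title", "")),
        author=_esc(front.get("author", "")),
        theme=front.get("theme", "default"),
        css=BASE_CSS,
        js=RUNTIME_JS,
        nav_html=_nav_html(doc),
        pages_html="\n".join(pages_html),
        sidebar_global=sidebar_global,
        footer=footer,
    )
    html = html.replace("\r\n", "\n").replace("\r", "\n")
    out_path = Path(out_path)
    try:
        data = html.encode("utf-8")
        out_path.write_bytes(data)
    except OSError as exc:
        raise OSError(f"cannot write dashboard to {out_path}: {exc}") from exc
    return {
        "bytes_written": len(data),
        "page_count": len(doc.sections),
        "asset_count": n_assets,
    }


_REF_RE = re.compile(
    r"""(?:src|href)\s*=\s*["'](?P<url>[^"']+)["']|url\(\s*['"]?(?P<cssurl>[^'")]+)""",
    re.IGNORECASE,
)


def external_references(html: str) -> list[str]:
    """All network references in asset/script/link positions.

    Self-contained output must return an empty list: data URIs, fragment
    anchors and relative download names are allowed; anything with a URL
    scheme (http, https, ftp, //cdn...) is reported.
    """
    refs = []
    for m in _REF_RE.finditer(html):
        url = (m.group("url") or m.group("cssurl") or "").strip()
        if not url or url.startswith(("data:", "#")):
            continue
        if re.match(r"^(?:[a-z][a-z0-9+.-]*:)?//", url) or re.match(
            r"^(?:https?|ftp|ws|wss):", url, re.IGNORECASE
        ):
            refs.append(url)
    return refs
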