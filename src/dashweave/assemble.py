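"""Assembly: Dashboard -> deterministic intermediate document.

The intermediate document is a markdown dialect with an ordered front-matter
header and fenced component blocks. It serves the same role an RMarkdown
file serves for notebook-style report generators: a complete, human-readable
serialization of the dashboard that the HTML renderer consumes. Keys and
sections are emitted in fixed order and floats in fixed precision, so
serialization is a pure function of the dashboard value: identical inputs
give byte-identical output (line endings are normalized to ``\\n``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

from .dispatch import ComponentFragment
from .errors import DashweaveError
from .layouts import LINKABLE_LAYOUTS, SlotPlan, assign_slots, capacity
from .linking import WiringEntry, compile_wiring
from .model import Dashboard, Page, SidebarContent

__all__ = [
    "ValidationIssue",
    "AssemblyError",
    "PageSection",
    "IntermediateDocument",
    "validate_dashboard",
    "assemble",
]


class ValidationIssue(NamedTuple):
    level: str  # "error" | "warning"
    location: str
    message: str


class AssemblyError(DashweaveError):
    """Raised by assemble() when validation reports errors; carries them all."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        lines = [f"  [{i.level}] {i.location}: {i.message}" for i in issues]
        super().__init__("dashboard failed validation:\n" + "\n".join(lines))


def validate_dashboard(db: Dashboard) -> list[ValidationIssue]:
    """Collect all structural problems; never raises.

    Errors: broken navbar/link/colormap references, duplicate element ids,
    capacity violations, link sources without data payloads. Warnings: empty
    pages, unused colormaps.
    """
    issues: list[ValidationIssue] = []
    err = lambda loc, msg: issues.append(ValidationIssue("error", loc, msg))
    warn = lambda loc, msg: issues.append(ValidationIssue("warning", loc, msg))

    seen_ids: set[str] = set()
    used_colormaps: set[str] = set()
    for page in db.pages.values():
        loc = f"page {page.id!r}"
        if not page.components:
            warn(loc, "page has no components")
        if len(page.components) > capacity(page.layout):
            err(loc, f"{len(page.components)} components exceed capacity of {page.layout!r}")
        for frag in page.components:
            if frag.element_id in seen_ids:
                err(loc, f"duplicate element id {frag.element_id!r}")
            seen_ids.add(frag.element_id)
            if not frag.body:
                err(loc, f"component {frag.element_id!r} has an empty body")
            if frag.colormap is not None:
                used_colormaps.add(frag.colormap)
                if frag.colormap not in db.colormaps:
                    err(loc, f"component {frag.element_id!r} declares unknown colormap {frag.colormap!r}")
        ids = {f.element_id for f in page.components}
        if page.links and page.layout not in LINKABLE_LAYOUTS:
            err(loc, f"layout {page.layout!r} is not linkable but page declares links")
        for link in page.links:
            for role, eid in (("source", link.source), ("target", link.target)):
                if eid not in ids:
                    err(loc, f"link {role} {eid!r} does not exist on this page")
            if link.source in ids:
                src = next(f for f in page.components if f.element_id == link.source)
                if src.data_payload is None:
                    err(loc, f"link source {link.source!r} has no data payload")

    for label, ref in db.navbar_items:
        if "://" not in ref and not ref.startswith("#") and ref not in db.pages:
            err("navbar", f"item {label!r} references missing page {ref!r}")

    for name in db.colormaps:
        if name not in used_colormaps:
            warn("colormaps", f"colormap {name!r} is registered but unused")
    return issues


@dataclass
class PageSection:
    page_id: str
    title: str
    layout: str
    menu: str | None
    slot_plan: SlotPlan
    fragments: list[ComponentFragment]
    sidebar: SidebarContent | None
    wiring: list[WiringEntry]


@dataclass
class IntermediateDocument:
    """Deterministic intermediate form of a dashboard, ready to render."""

    front_matter: list[tuple[str, str]]
    colormaps: dict[str, dict[str, str]]
    navbar_items: list[tuple[str, str]]
    sidebar_global: SidebarContent | None
    sections: list[PageSection] = field(default_factory=list)

    def serialize(self) -> str:
        """Markdown-dialect text; byte-identical for a fixed dashboard."""
        out: list[str] = ["---"]
        for key, value in self.front_matter:
            out.append(f"{key}: {json.dumps(value, ensure_ascii=True)}")
        out.append("---")
        if self.colormaps:
            out += ["", "```colormaps", _j(self.colormaps), "```"]
        if self.navbar_items:
            out += ["", "```navbar", _j([list(t) for t in self.navbar_items]), "```"]
        if self.sidebar_global is not None:
            out += _sidebar_blocks(self.sidebar_global, "document")
        for sec in self.sections:
            head_attrs = f"{{#{sec.page_id} layout={sec.layout}"
            if sec.menu:
                head_attrs += f" menu={json.dumps(sec.menu)}"
            head_attrs += "}"
            out += ["", f"# {sec.title} {head_attrs}"]
            slot_of = {
                s.element_id: s.name for s in sec.slot_plan.slots if s.element_id
            }
            if sec.sidebar is not None:
                out += _sidebar_blocks(sec.sidebar, sec.page_id)
            for frag in sec.fragments:
                title = json.dumps(frag.title or "")
                out += [
                    "",
                    f"## component {{id={frag.element_id} kind={frag.kind} "
                    f"slot={slot_of.get(frag.element_id, '-')} title={title}}}",
                    "",
                    "::: body",
                    frag.body,
                    ":::",
                ]
                if frag.assets:
                    out += [
                        "",
                        f"```assets {frag.element_id}",
                        _j([
                            {"id": a.asset_id, "media_type": a.media_type, "b64": a.payload_b64}
                            for a in frag.assets
                        ]),
                        "```",
                    ]
                if frag.data_payload is not None:
                    out += ["", f"```data {frag.element_id}", _j(frag.data_payload), "```"]
            if sec.wiring:
                out += [
                    "",
                    f"```wiring {sec.page_id}",
                    _j([w.to_dict() for w in sec.wiring]),
                    "```",
                ]
        return "\n".join(out).replace("\r\n", "\n").replace("\r", "\n") + "\n"


def _j(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=True, allow_nan=False)


def _sidebar_blocks(sidebar: SidebarContent, owner: str) -> list[str]:
    out = ["", f"## sidebar {{owner={owner} scope={sidebar.scope}}}"]
    for frag in sidebar.fragments:
        out += ["", "::: body", frag.body, ":::"]
    return out


def assemble(db: Dashboard) -> IntermediateDocument:
    """Assemble the dashboard into an :class:`IntermediateDocument`.

    Pages are emitted in insertion order; fragments in slot order; the
    wiring table of each linkable page is compiled and attached. Validation
    errors abort with the full issue list (warnings are allowed and logged).

    Raises
    ------
    AssemblyError
        If :func:`validate_dashboard` reports any error-level issue.
    """
    issues = validate_dashboard(db)
    errors = [i for i in issues if i.level == "error"]
    if errors:
        raise AssemblyError(errors)

    front = [
        ("title", db.title),
        ("author", db.author),
        ("theme", db.theme),
        ("interactive", "true" if db.interactive else "false"),
    ]
    doc = IntermediateDocument(
        front_matter=front,
        colormaps={k: dict(v) for k, v in db.colormaps.items()},
        navbar_items=list(db.navbar_items),
        sidebar_global=db.sidebar_global,
    )
    for page in db.pages.values():
        plan = assign_slots(page.layout, page.component_ids)
        doc.sections.append(
            PageSection(
                page_id=page.id,
                title=page.title,
                layout=page.layout,
                menu=page.menu,
                slot_plan=plan,
                fragments=list(page.components),
                sidebar=page.sidebar,
                wiring=compile_wiring(page),
            )
        )
    return doc
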