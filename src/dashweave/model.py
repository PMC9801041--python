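"""The dashboard document model and its iterative mutation operations.

A :class:`Dashboard` is built up step by step from within an analysis
pipeline: create it empty, add pages with layouts, drop content onto pages
as results become available, register document-wide colormaps, then assemble
and render (:mod:`dashweave.assemble`, :mod:`dashweave.render`). All
mutation operations log at info level; replacements and no-op removals log
warnings instead of raising, matching an iterative workflow in which later
pipeline stages refine earlier pages. Overflowing a layout's capacity, by
contrast, is a hard error: components are never silently dropped.

Element ids are ordinal-deterministic (``<page_id>-c<ordinal>``), never
random, so repeated builds of the same pipeline are byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Any

from .dispatch import ComponentFragment, dispatch_content
from .errors import CapacityError, ConfigurationError
from .layouts import PAGE_LAYOUTS, capacity
from .linking import LinkSpec, validate_link

__all__ = [
    "THEMES",
    "Dashboard",
    "Page",
    "SidebarContent",
    "create_dashboard",
]

logger = logging.getLogger("dashweave")

#: Fixed theme set; a theme selects an emitted stylesheet token only and
#: never changes document structure.
THEMES = ("default", "dark", "light")

_SLUG_RE = re.compile(r"^[a-z0-9_]+$")
_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


def _check_slug(value: str, what: str) -> str:
    """Lowercase and validate an id. Characters outside [a-z0-9_] are an
    error rather than auto-mangled: predictability over convenience."""
    if not isinstance(value, str) or not value:
        raise ConfigurationError(f"{what} must be a non-empty string, got {value!r}")
    slug = value.lower()
    if not _SLUG_RE.match(slug):
        raise ConfigurationError(
            f"{what} {value!r} is not slug-safe: only lowercase alphanumerics "
            "and underscore are allowed"
        )
    return slug


def _check_colormap(name: str, mapping: dict) -> dict[str, str]:
    if not mapping:
        raise ConfigurationError(f"colormap {name!r} is empty")
    out: dict[str, str] = {}
    for level, color in mapping.items():
        level = str(level)
        if level in out:
            raise ConfigurationError(f"colormap {name!r}: duplicate level {level!r}")
        if not isinstance(color, str) or not _HEX_RE.match(color):
            raise ConfigurationError(
                f"colormap {name!r}: {color!r} for level {level!r} is not a "
                "6-digit hex color like '#1f77b4'"
            )
        out[level] = color.lower()
    return out


@dataclass
class SidebarContent:
    """Static content shown in a fixed-width left rail, attached either to
    the whole document (scope ``global``) or to one page (scope ``local``)."""

    scope: str
    fragments: list[ComponentFragment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scope not in ("global", "local"):
            raise ConfigurationError(
                f"sidebar scope must be 'global' or 'local', got {self.scope!r}"
            )


@dataclass
class Page:
    id: str
    title: str
    layout: str
    menu: str | None = None
    sidebar: SidebarContent | None = None
    components: list[ComponentFragment] = field(default_factory=list)
    links: list[LinkSpec] = field(default_factory=list)
    _next_ordinal: int = 1

    @property
    def component_ids(self) -> list[str]:
        return [f.element_id for f in self.components]


@dataclass
class Dashboard:
    """Root document: metadata plus ordered pages, colormaps and navigation.

    Prefer :func:`create_dashboard` over direct construction; the factory
    validates the theme and starts from an explicitly empty document.
    """

    title: str
    author: str = ""
    theme: str = "default"
    interactive: bool = False
    pages: dict[str, Page] = field(default_factory=dict)
    colormaps: dict[str, dict[str, str]] = field(default_factory=dict)
    navbar_items: list[tuple[str, str]] = field(default_factory=list)
    sidebar_global: SidebarContent | None = None

    # -- pages ------------------------------------------------------------

    def add_page(
        self,
        page_id: str,
        title: str,
        layout: str,
        menu: str | None = None,
    ) -> "Dashboard":
        """Add a page with one of the four layouts.

        Re-adding an existing id replaces the page (components and links
        included) with a warning.
        """
        page_id = _check_slug(page_id, "page id")
        if layout not in PAGE_LAYOUTS:
            raise ConfigurationError(
                f"unknown layout {layout!r}; valid layouts: {', '.join(PAGE_LAYOUTS)}"
            )
        if page_id in self.pages:
            logger.warning("page %r already exists and is replaced", page_id)
        else:
            logger.info("adding page %r (layout %s)", page_id, layout)
        self.pages[page_id] = Page(id=page_id, title=title, layout=layout, menu=menu)
        return self

    def remove_page(self, page_id: str) -> "Dashboard":
        """Remove a page; navbar items pointing at it are dropped too.
        Removing a missing id is a warning, not an error."""
        if page_id not in self.pages:
            logger.warning("remove_page: no page %r; nothing removed", page_id)
            return self
        del self.pages[page_id]
        kept = [(lab, ref) for lab, ref in self.navbar_items if ref != page_id]
        if len(kept) != len(self.navbar_items):
            logger.warning("dropping navbar item(s) referencing removed page %r", page_id)
            self.navbar_items = kept
        logger.info("removed page %r", page_id)
        return self

    def page(self, page_id: str) -> Page:
        try:
            return self.pages[page_id]
        except KeyError:
            raise ConfigurationError(
                f"no page {page_id!r}; existing pages: "
                + (", ".join(self.pages) or "none")
            ) from None

    # -- components -------------------------------------------------------

    def add_component(
        self, page_id: str, content: Any, title: str | None = None
    ) -> "Dashboard":
        """Dispatch *content* (see :func:`dashweave.dispatch.dispatch_content`)
        and append the fragment to the page, assigning the deterministic
        element id ``<page_id>-c<ordinal>``."""
        page = self.page(page_id)
        cap = capacity(page.layout)
        if len(page.components) + 1 > cap:
            raise CapacityError(
                f"page {page_id!r} uses layout {page.layout!r} with capacity "
                f"{int(cap)}; cannot add component {len(page.components) + 1}"
            )
        fragment = dispatch_content(content, title)
        fragment.element_id = f"{page_id}-c{page._next_ordinal}"
        page._next_ordinal += 1
        page.components.append(fragment)
        logger.info(
            "added %s component %r to page %r", fragment.kind, fragment.element_id, page_id
        )
        return self

    # -- colormaps and navigation -----------------------------------------

    def add_colormap(self, name: str, mapping: dict) -> "Dashboard":
        """Register a document-wide category->hex-color mapping. Every
        component declaring this name resolves identical colors at render
        time. Re-registering a name is an error; remove it first."""
        if name in self.colormaps:
            raise ConfigurationError(
                f"colormap {name!r} is already registered; remove it first "
                "with remove_colormap()"
            )
        self.colormaps[name] = _check_colormap(name, mapping)
        logger.info("registered colormap %r (%d levels)", name, len(mapping))
        return self

    def remove_colormap(self, name: str) -> "Dashboard":
        if name not in self.colormaps:
            logger.warning("remove_colormap: no colormap %r", name)
            return self
        del self.colormaps[name]
        return self

    def add_navbar_item(self, label: str, ref: str) -> "Dashboard":
        """Add a navigation bar item: *ref* is either a URL (contains
        ``://`` or starts with ``#``) or the id of an existing page."""
        if "://" not in ref and not ref.startswith("#") and ref not in self.pages:
            raise ConfigurationError(
                f"navbar item {label!r} references unknown page id {ref!r}"
            )
        self.navbar_items.append((label, ref))
        logger.info("added navbar item %r -> %r", label, ref)
        return self

    def add_to_sidebar(
        self, content: Any, title: str | None = None, page_id: str | None = None
    ) -> "Dashboard":
        """Attach content to the global sidebar, or to a page's local
        sidebar when *page_id* is given."""
        fragment = dispatch_content(content, title)
        if page_id is None:
            if self.sidebar_global is None:
                self.sidebar_global = SidebarContent(scope="global")
            sidebar = self.sidebar_global
        else:
            page = self.page(page_id)
            if page.sidebar is None:
                page.sidebar = SidebarContent(scope="local")
            sidebar = page.sidebar
        fragment.element_id = f"sidebar-{page_id or 'global'}-c{len(sidebar.fragments) + 1}"
        sidebar.fragments.append(fragment)
        return self

    # -- links -------------------------------------------------------------

    def add_link(self, page_id: str, spec: LinkSpec) -> "Dashboard":
        """Declare a linked view on a page (see :mod:`dashweave.linking`)."""
        page = self.page(page_id)
        validate_link(spec, page)
        page.links.append(spec)
        logger.info("added %s link %s -> %s on page %r", spec.channel, spec.source, spec.target, page_id)
        return self


def create_dashboard(
    title: str,
    author: str = "",
    theme: str = "default",
    interactive: bool = False,
) -> Dashboard:
    """Initialize an empty dashboard: zero pages, colormaps and navbar items.

    Raises
    ------
    ConfigurationError
        If *theme* is not one of :data:`THEMES`.
    """
    if theme not in THEMES:
        raise ConfigurationError(
            f"unknown theme {theme!r}; valid themes: {', '.join(THEMES)}"
        )
    logger.info("created dashboard %r (theme %s)", title, theme)
    return Dashboard(title=title, author=author, theme=theme, interactive=bool(interactive))
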