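"""Generic content dispatch: convert heterogeneous content into fragments.

This is the mechanism that lets one ``add_component`` call accept markdown
text, an image path, a table, a declarative figure, or a zero-argument
callable, and that makes template extensions possible: an extension builds
whole pages purely by passing such content through the public operations.

Dispatch rules (by Python type):

* ``str`` -- markdown text, body is the input verbatim. Exception: a string
  that names an *existing* file with a recognized extension is dispatched as
  that file (image or table), mirroring path-based dispatch.
* ``pathlib.Path`` -- always a file; .png/.jpg/.jpeg/.svg embed as a base64
  image asset, .csv/.tsv load as a table. A missing file is an error.
* ``pandas.DataFrame`` or a list of dicts -- a table: a markdown-rendered
  body capped at :data:`TABLE_ROW_CAP` rows plus the full records in
  ``data_payload`` (used by linked views and downloads).
* :class:`~dashweave.figures.FigureSpec` -- a figure, rendered to SVG at
  assembly time; the spec itself is kept on the fragment.
* zero-argument callable -- invoked exactly once at dispatch time; its
  returned markdown becomes the body verbatim (kind ``injected``). Eager
  evaluation means a pipeline failure surfaces where it occurs.

Dispatch is pure for non-callable inputs: the same input yields an identical
fragment, asset bytes included.
"""

from __future__ import annotations

import base64
import mimetypes
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from .errors import DispatchError
from .figures import FigureSpec

__all__ = ["ComponentFragment", "Asset", "dispatch_content", "TABLE_ROW_CAP", "records_to_markdown"]

#: Maximum rows shown in a table fragment's static body; the full data is
#: always carried in ``data_payload``.
TABLE_ROW_CAP = 20

_IMAGE_EXTS = {".png": "image/png", ".jpg": "image/jpeg", ".jpeg": "image/jpeg", ".svg": "image/svg+xml"}
_TABLE_EXTS = {".csv": ",", ".tsv": "\t"}

FRAGMENT_KINDS = ("text", "image", "table", "figure", "injected")


@dataclass(frozen=True)
class Asset:
    asset_id: str
    media_type: str
    payload_b64: str


@dataclass
class ComponentFragment:
    """The dispatched, emit-ready unit of page content.

    ``element_id`` is assigned by the dashboard when the fragment is added to
    a page (deterministic ``<page_id>-c<ordinal>``); ``body`` is markdown (or
    verbatim injected markup); ``assets`` are embedded base64 payloads;
    ``data_payload`` holds the records linked views aggregate over.
    """

    kind: str
    title: str | None = None
    element_id: str = ""
    body: str = ""
    assets: list[Asset] = field(default_factory=list)
    data_payload: list[dict] | None = None
    figure: FigureSpec | None = None

    @property
    def colormap(self) -> str | None:
        """Document colormap this fragment declares, if any."""
        return self.figure.colormap if self.figure is not None else None


def _jsonable(v: Any) -> Any:
    import numpy as np

    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, float) and v != v:  # NaN -> null for JSON islands
        return None
    return v


def records_to_markdown(records: list[dict], row_cap: int = TABLE_ROW_CAP) -> str:
    """Render records as a GFM table, column order = input order, capped rows."""
    if not records:
        return "*(empty table)*"
    cols = list(records[0].keys())

    def cell(v: Any) -> str:
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v).replace("|", "\\|").replace("\n", " ")

    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for rec in records[:row_cap]:
        lines.append("| " + " | ".join(cell(rec.get(c, "")) for c in cols) + " |")
    if len(records) > row_cap:
        lines.append("")
        lines.append(f"*{len(records) - row_cap} further rows omitted; full data attached.*")
    return "\n".join(lines)


def _table_fragment(df: pd.DataFrame, title: str | None) -> ComponentFragment:
    records = [
        {str(k): _jsonable(v) for k, v in rec.items()}
        for rec in df.to_dict(orient="records")
    ]
    return ComponentFragment(
        kind="table",
        title=title,
        body=records_to_markdown(records),
        data_payload=records,
    )


def _image_fragment(path: Path, title: str | None) -> ComponentFragment:
    media = _IMAGE_EXTS[path.suffix.lower()]
    payload = base64.b64encode(path.read_bytes()).decode("ascii")
    asset = Asset(asset_id=path.name, media_type=media, payload_b64=payload)
    return ComponentFragment(
        kind="image",
        title=title,
        body=f"![{title or path.name}](asset:{path.name})",
        assets=[asset],
    )


def _file_fragment(path: Path, title: str | None) -> ComponentFragment:
    if not path.exists():
        raise FileNotFoundError(f"content file does not exist: {path}")
    ext = path.suffix.lower()
    if ext in _IMAGE_EXTS:
        return _image_fragment(path, title)
    if ext in _TABLE_EXTS:
        df = pd.read_csv(path, sep=_TABLE_EXTS[ext])
        return _table_fragment(df, title)
    raise DispatchError(
        f"unsupported file extension {ext!r}; supported: "
        + ", ".join(sorted(_IMAGE_EXTS | _TABLE_EXTS.keys()))
    )


def _looks_like_file(s: str) -> bool:
    if "\n" in s or len(s) > 4096:
        return False
    p = Path(s)
    return p.suffix.lower() in (_IMAGE_EXTS.keys() | _TABLE_EXTS.keys()) and p.exists()


def dispatch_content(content: Any, title: str | None = None) -> ComponentFragment:
    """Convert *content* into a :class:`ComponentFragment` (see module docs).

    Raises
    ------
    FileNotFoundError
        For a ``Path`` that does not exist.
    DispatchError
        For unsupported content types, unsupported file extensions, or a
        callable that raises (the original error is chained).
    """
    if isinstance(content, ComponentFragment):
        return content
    if isinstance(content, FigureSpec):
        import json

        body = "```figure\n" + json.dumps(content.to_dict(), sort_keys=True) + "\n```"
        return ComponentFragment(
            kind="figure",
            title=title or content.title or None,
            body=body,
            figure=content,
            data_payload=content.data,
        )
    if isinstance(content, Path):
        return _file_fragment(content, title)
    if isinstance(content, str):
        if _looks_like_file(content):
            return _file_fragment(Path(content), title)
        if not content.strip():
            raise DispatchError("text content is empty")
        return ComponentFragment(kind="text", title=title, body=content)
    if isinstance(content, pd.DataFrame):
        return _table_fragment(content, title)
    if isinstance(content, list) and content and all(isinstance(r, dict) for r in content):
        return _table_fragment(pd.DataFrame(content), title)
    if callable(content):
        try:
            result = content()
        except Exception as exc:
            name = getattr(content, "__name__", repr(content))
            raise DispatchError(
                f"injected content callable {name!r} raised {type(exc).__name__}: {exc}"
            ) from exc
        if not isinstance(result, str) or not result.strip():
            name = getattr(content, "__name__", repr(content))
            raise DispatchError(
                f"injected content callable {name!r} must return non-empty markdown text"
            )
        return ComponentFragment(kind="injected", title=title, body=result)
    raise DispatchError(
        f"unsupported content type {type(content).__name__!r}; supported kinds: "
        "markdown str, image/table file path, DataFrame or record list, "
        "FigureSpec, zero-argument callable"
    )
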