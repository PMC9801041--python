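"""Declarative linked views: selections in one component update another.

A :class:`LinkSpec` declares a one-way, intra-page link: when the user
selects data points in the *source* component, the *target* component is
updated. Two update channels exist:

``subset_recompute``
    The target shows an aggregation (count / mean / median / sum of a named
    variable, grouped by a category) recomputed over the selected subset of
    the source's data records. An empty selection restores the full-data
    view.
``color_by_selection``
    The selected source record names a variable (e.g. a gene chosen from a
    marker table) and the target's color encoding switches to that variable.

Links are only allowed on linkable layouts (focal_left, grid_2x2).
:func:`compile_wiring` turns a validated page's links into a flat wiring
table that is embedded in the rendered HTML as a JSON island and consumed by
one small data-driven script -- no per-link code generation, so output stays
auditable and deterministic. :func:`apply_selection` is the reference
(server-side) implementation of the same update semantics, used to verify
the protocol against brute-force recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import LinkError
from .layouts import LINKABLE_LAYOUTS

__all__ = [
    "LinkSpec",
    "WiringEntry",
    "AGGREGATION_FUNS",
    "compile_wiring",
    "apply_selection",
    "resolve_color_variable",
]

AGGREGATION_FUNS = ("count", "mean", "median", "sum")
CHANNELS = ("subset_recompute", "color_by_selection")
EVENTS = ("selection",)


@dataclass(frozen=True)
class LinkSpec:
    """One-way link between two components on the same page.

    Parameters
    ----------
    source, target:
        Component element ids; must be distinct and on the same page.
    channel:
        ``subset_recompute`` or ``color_by_selection``.
    aggregate, variable, by:
        For ``subset_recompute``: the aggregation function, the aggregated
        variable and the grouping category (``by`` defaults to ``variable``
        for counts). For ``color_by_selection``: ``variable`` names the
        source-record field whose selected value becomes the target's color
        variable.
    event:
        Only ``selection`` in v1; hover/zoom are extension points.
    """

    source: str
    target: str
    channel: str = "subset_recompute"
    aggregate: str | None = None
    variable: str | None = None
    by: str | None = None
    event: str = "selection"

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise LinkError(f"unknown event {self.event!r}; valid events: {', '.join(EVENTS)}")
        if self.channel not in CHANNELS:
            raise LinkError(f"unknown channel {self.channel!r}; valid channels: {', '.join(CHANNELS)}")
        if self.source == self.target:
            raise LinkError(f"self-link on component {self.source!r} is not allowed")
        if self.channel == "subset_recompute":
            if self.aggregate not in AGGREGATION_FUNS:
                raise LinkError(
                    f"subset_recompute requires an aggregation from "
                    f"{{{', '.join(AGGREGATION_FUNS)}}}, got {self.aggregate!r}"
                )
            if not self.variable:
                raise LinkError("subset_recompute requires a named variable")
        if self.channel == "color_by_selection" and not self.variable:
            raise LinkError("color_by_selection requires the source field naming the color variable")

    @property
    def group_by(self) -> str | None:
        if self.channel != "subset_recompute":
            return None
        return self.by or self.variable


@dataclass(frozen=True)
class WiringEntry:
    """One row of the compiled wiring table."""

    source: str
    event: str
    target: str
    update: str  # update function identifier: recompute_bars | recolor
    aggregation: dict | None
    encoding: str | None

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "event": self.event,
            "target": self.target,
            "update": self.update,
            "aggregation": self.aggregation,
            "encoding": self.encoding,
        }


def validate_link(spec: LinkSpec, page) -> None:
    """Check a link against its page: linkable layout, known distinct ids."""
    if page.layout not in LINKABLE_LAYOUTS:
        raise LinkError(
            f"layout {page.layout!r} of page {page.id!r} is not linkable; "
            f"linkable layouts: {', '.join(LINKABLE_LAYOUTS)}"
        )
    ids = {frag.element_id for frag in page.components}
    for role, eid in (("source", spec.source), ("target", spec.target)):
        if eid not in ids:
            raise LinkError(
                f"link {role} {eid!r} is not a component of page {page.id!r} "
                f"(components: {', '.join(sorted(ids)) or 'none'})"
            )


def compile_wiring(page) -> list[WiringEntry]:
    """Compile a validated page's links into its wiring table.

    Raises
    ------
    LinkError
        If a link references a component without a data payload (there is
        then nothing to select from or aggregate over).
    """
    frags = {f.element_id: f for f in page.components}
    entries: list[WiringEntry] = []
    for spec in page.links:
        validate_link(spec, page)
        src = frags[spec.source]
        if src.data_payload is None:
            raise LinkError(
                f"link source {spec.source!r} has no data payload to select from"
            )
        if spec.channel == "subset_recompute":
            entries.append(
                WiringEntry(
                    source=spec.source,
                    event=spec.event,
                    target=spec.target,
                    update="recompute_bars",
                    aggregation={
                        "fun": spec.aggregate,
                        "variable": spec.variable,
                        "by": spec.group_by,
                    },
                    encoding=None,
                )
            )
        else:
            tgt = frags[spec.target]
            if tgt.data_payload is None:
                raise LinkError(
                    f"link target {spec.target!r} has no data payload to re-encode"
                )
            encoding = None
            if tgt.figure is not None:
                encoding = tgt.figure.value_var or tgt.figure.category_var
            entries.append(
                WiringEntry(
                    source=spec.source,
                    event=spec.event,
                    target=spec.target,
                    update="recolor",
                    aggregation={"variable": spec.variable},
                    encoding=encoding,
                )
            )
    return entries


def _levels(records: Sequence[dict], by: str) -> list:
    return sorted({r[by] for r in records if r.get(by) is not None}, key=str)


def apply_selection(
    entry: WiringEntry,
    records: Sequence[dict],
    selected_indices: Sequence[int] | None,
) -> dict:
    """Reference update semantics for a ``recompute_bars`` wiring entry.

    Aggregates the selected subset of *records* (the source component's data
    payload) per level of the grouping category. Levels are those observed in
    the **full** data, in sorted order, so an empty level shows count 0 (or
    ``nan`` for mean/median of no records). ``selected_indices`` of ``None``
    or empty means no active selection: the full-data view is restored.
    """
    if entry.update != "recompute_bars":
        raise LinkError(f"apply_selection handles recompute_bars entries, got {entry.update!r}")
    agg = entry.aggregation or {}
    fun, var, by = agg.get("fun"), agg.get("variable"), agg.get("by")
    subset = (
        list(records)
        if not selected_indices
        else [records[i] for i in selected_indices]
    )
    out: dict = {}
    for level in _levels(records, by):
        vals = [r.get(var) for r in subset if r.get(by) == level]
        if fun == "count":
            out[level] = len(vals)
            continue
        nums = [float(v) for v in vals if v is not None]
        if not nums:
            out[level] = math.nan
        elif fun == "mean":
            out[level] = sum(nums) / len(nums)
        elif fun == "sum":
            out[level] = sum(nums)
        elif fun == "median":
            s = sorted(nums)
            m = len(s) // 2
            out[level] = s[m] if len(s) % 2 else (s[m - 1] + s[m]) / 2.0
        else:
            raise LinkError(f"unknown aggregation function {fun!r}")
    return out


def resolve_color_variable(
    entry: WiringEntry, source_records: Sequence[dict], selected_index: int
) -> str:
    """Reference semantics for a ``recolor`` entry: the selected source
    record's ``variable`` field names the target's new color variable."""
    if entry.update != "recolor":
        raise LinkError(f"resolve_color_variable handles recolor entries, got {entry.update!r}")
    var = (entry.aggregation or {}).get("variable")
    value = source_records[selected_index].get(var)
    if value is None:
        raise LinkError(f"selected record has no field {var!r}")
    return str(value)
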