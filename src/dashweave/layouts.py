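"""Page layouts: capacities and slot geometry.

Four slot-bearing page layouts are supported:

``storyboard``
    Unlimited capacity; one full-width slot per component in sequence order,
    for a narrated sequence of visualizations.
``tabset``
    Unlimited capacity; one tab per component in insertion order, for many
    components without scrolling.
``focal_left``
    Up to three components; the first fills a left column at 2/3 page width,
    the remaining (at most two) stack equally in the right column. Linkable.
``grid_2x2``
    Up to four components in a row-major 2x2 grid. Linkable.

A sidebar is not a slot-bearing layout: it is content attached to a page or
to the whole document and occupies a fixed-width left rail at render time
(see :mod:`dashweave.model`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import CapacityError, ConfigurationError

__all__ = [
    "PAGE_LAYOUTS",
    "LINKABLE_LAYOUTS",
    "FOCAL_WIDTH_FRACTION",
    "Slot",
    "SlotPlan",
    "capacity",
    "assign_slots",
]

#: The four slot-bearing page layouts.
PAGE_LAYOUTS = ("storyboard", "tabset", "focal_left", "grid_2x2")

#: Layouts on which linked views may be declared.
LINKABLE_LAYOUTS = ("focal_left", "grid_2x2")

#: Width fraction of the highlighted component in a focal_left page. A fixed
#: convention, recorded once so an alternate geometry is a one-line change.
FOCAL_WIDTH_FRACTION = 2.0 / 3.0

_CAPACITY = {
    "storyboard": math.inf,
    "tabset": math.inf,
    "focal_left": 3,
    "grid_2x2": 4,
}


@dataclass(frozen=True)
class Slot:
    """One rectangular slot of a slot plan.

    ``width`` and ``height`` are fractions of the page content area;
    ``element_id`` is the component placed in the slot, or ``None`` for an
    intentionally empty cell (only grid_2x2 emits empty cells).
    """

    name: str
    width: float
    height: float
    element_id: str | None


@dataclass(frozen=True)
class SlotPlan:
    layout: str
    slots: tuple[Slot, ...] = field(default_factory=tuple)


def capacity(layout: str) -> int | float:
    """Component capacity of *layout*: a positive integer, or ``math.inf``
    for the unbounded layouts (storyboard, tabset).

    Raises
    ------
    ConfigurationError
        If *layout* is not one of the four page layouts.
    """
    try:
        return _CAPACITY[layout]
    except KeyError:
        raise ConfigurationError(
            f"unknown layout {layout!r}; valid layouts: {', '.join(PAGE_LAYOUTS)}"
        ) from None


def assign_slots(layout: str, component_ids: list[str]) -> SlotPlan:
    """Assign components to layout slots, deterministically and order-preserving.

    storyboard/tabset get one full slot per component; focal_left places the
    first component in a 2/3-width left column with the rest stacked equally
    on the right; grid_2x2 fills row-major and emits missing cells empty.
    """
    cap = capacity(layout)
    if len(component_ids) > cap:
        raise CapacityError(
            f"layout {layout!r} admits at most {int(cap)} components, "
            f"got {len(component_ids)}"
        )
    if layout in ("storyboard", "tabset"):
        slots = [
            Slot(f"slot_{i + 1}", 1.0, 1.0, eid)
            for i, eid in enumerate(component_ids)
        ]
    elif layout == "focal_left":
        slots = []
        if component_ids:
            slots.append(Slot("focal", FOCAL_WIDTH_FRACTION, 1.0, component_ids[0]))
            rest = component_ids[1:]
            for i, eid in enumerate(rest):
                slots.append(
                    Slot(
                        f"side_{i + 1}",
                        1.0 - FOCAL_WIDTH_FRACTION,
                        1.0 / len(rest),
                        eid,
                    )
                )
    else:  # grid_2x2: always four cells, row-major
        padded = list(component_ids) + [None] * (4 - len(component_ids))
        slots = [
            Slot(f"r{i // 2}c{i % 2}", 0.5, 0.5, padded[i]) for i in range(4)
        ]
    return SlotPlan(layout=layout, slots=tuple(slots))
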