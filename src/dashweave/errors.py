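"""Exception hierarchy.

All package errors derive from :class:`DashweaveError` so pipeline code can
catch one base class. Messages are written to be actionable: they name the
offending value and, where a closed set exists, enumerate the valid options.
"""

__all__ = [
    "DashweaveError",
    "ConfigurationError",
    "CapacityError",
    "DispatchError",
    "LinkError",
    "OptionError",
    "SimulationError",
]


class DashweaveError(Exception):
    """Base class for all dashweave errors."""


class ConfigurationError(DashweaveError):
    """Invalid dashboard configuration: unknown theme/layout, bad slug, bad color."""


class CapacityError(DashweaveError):
    """A page layout's component capacity would be exceeded."""


class DispatchError(DashweaveError):
    """Content could not be converted into a component fragment."""


class LinkError(DashweaveError):
    """An invalid linked-view specification."""


class OptionError(DashweaveError):
    """A page-template option is missing or invalid."""


class SimulationError(DashweaveError):
    """An invalid synthetic-data simulation specification."""
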