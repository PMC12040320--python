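"""Exception hierarchy shared across the package."""


class PlacerepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlacerepError, ValueError):
    """Raised when parameters describe an infeasible configuration."""


class DataError(PlacerepError, ValueError):
    """Raised when input data violate a structural precondition."""


class SimulationError(PlacerepError, RuntimeError):
    """Raised when a synthetic-session simulation cannot proceed."""


class RegionLookupError(PlacerepError, KeyError):
    """Raised when a region id is unknown to the geometry."""
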