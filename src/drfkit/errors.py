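"""Exception hierarchy shared across the toolkit."""


class DrfKitError(Exception):
    """Base class for all drfkit errors."""


class GeometryError(DrfKitError):
    """Degenerate or out-of-envelope sensor/segment geometry."""


class TraceError(DrfKitError):
    """A force trace does not satisfy the preconditions of an operation."""


class FitError(DrfKitError):
    """A least-squares fit failed to converge or is degenerate."""


class ConfigError(DrfKitError):
    """Invalid configuration (units, distribution tags, bounds)."""
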