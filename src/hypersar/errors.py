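"""Exception types raised across the package."""


class HypersarError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(HypersarError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(HypersarError, ValueError):
    """A geometric configuration is degenerate (e.g. target on an antenna)."""


class ZeroFieldError(HypersarError, ValueError):
    """A field is identically zero where a nonzero field is required."""


class ConfigError(HypersarError, ValueError):
    """A configuration file or object fails schema validation."""


class TrainingDivergedError(HypersarError, RuntimeError):
    """Training produced a non-finite loss."""
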