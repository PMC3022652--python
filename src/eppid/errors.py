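"""Exception hierarchy shared across the package."""


class EppidError(Exception):
    """Base class for all package errors."""


class ValidationError(EppidError, ValueError):
    """Input violates a documented invariant (bad threshold, negative dN, ...)."""


class ParseError(EppidError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(EppidError, ValueError):
    """A scenario or run configuration is infeasible or inconsistent."""
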