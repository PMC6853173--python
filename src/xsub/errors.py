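"""Exception hierarchy shared across the package."""


class XsubError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XsubError, ValueError):
    """A file or table violates a documented format contract.

    Messages name the offending file/row/identifier so that bad inputs are
    diagnosable without a debugger.
    """


class ConfigError(XsubError, ValueError):
    """A simulation or pipeline configuration violates an invariant."""
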