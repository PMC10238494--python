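"""Exception types shared across the package."""


class MrmKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrmKitError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(MrmKitError, ValueError):
    """Input data (sequences, tables, files) is malformed or inconsistent."""
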