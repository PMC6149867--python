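"""Exception hierarchy shared across the toolkit."""


class DioicaError(Exception):
    """Base class for all errors raised by dioica."""


class ConfigurationError(DioicaError):
    """A configuration value is missing, out of range, or inconsistent."""


class InputError(DioicaError):
    """An input file or in-memory input violates the documented contract."""
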