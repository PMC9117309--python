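"""Exception hierarchy used across the package."""


class NetcurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetcurvError):
    """A configuration value (spec field, density grid, ...) is invalid."""


class InputError(NetcurvError):
    """An input object or file violates its contract."""


class ValidationError(InputError):
    """A parsed file failed structural validation."""
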