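"""Exception hierarchy shared by all pipeline stages."""


class PairedTagError(Exception):
    """Base class for all package-raised errors."""


class ConfigurationError(PairedTagError):
    """A configuration value is invalid or internally inconsistent."""


class InputError(PairedTagError):
    """An input file or in-memory input violates a stage precondition."""
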