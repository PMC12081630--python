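"""Exception types shared across the package."""


class SeedcapError(Exception):
    """Base class for all seedcap errors."""


class ConfigurationError(SeedcapError):
    """A configuration value is invalid or inconsistent."""


class FormatError(SeedcapError):
    """An input file or array does not have the expected layout."""


class DegenerateDataError(SeedcapError):
    """The data admit no meaningful answer (e.g. zero-variance seed)."""
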