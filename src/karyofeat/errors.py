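"""Exception hierarchy shared across the pipeline."""


class KaryofeatError(Exception):
    """Base class for all package errors."""


class FormatError(KaryofeatError):
    """A file does not conform to its declared dialect."""


class ConfigError(KaryofeatError):
    """Inconsistent or incomplete run configuration."""


class SpecError(KaryofeatError):
    """An invalid simulation specification (overlapping features, bad sizes)."""
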