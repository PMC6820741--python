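"""Exception hierarchy shared across the package."""


class LupusCmapError(Exception):
    """Base class for all package errors."""


class FormatError(LupusCmapError):
    """A file could not be parsed as the expected on-disk format."""


class ValidationError(LupusCmapError):
    """Parsed or constructed data violates a documented invariant."""
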