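"""Exception hierarchy shared across the toolkit."""


class TcrkitError(Exception):
    """Base class for all toolkit-specific errors."""


class SchemaError(TcrkitError):
    """A mandatory column is missing or an input file has an unusable layout."""


class EmptyInputError(TcrkitError):
    """An operation received no usable records."""


class FormatError(TcrkitError):
    """A file could not be recognized as any supported dialect."""


class MissingAnnotationError(TcrkitError):
    """Gene-level statistics were requested but no gene calls are present."""


class StageError(TcrkitError):
    """A motif-matrix operation was applied at the wrong pipeline stage."""
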