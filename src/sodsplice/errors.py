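"""Exception hierarchy shared across the pipeline."""


class SodspliceError(Exception):
    """Base class for all package errors."""


class FormatError(SodspliceError):
    """A file violated the expected on-disk format."""


class ConfigurationError(SodspliceError):
    """Invalid or inconsistent configuration values."""


class InputError(SodspliceError):
    """Invalid in-memory input (bad residues, non-symmetric matrix, ...)."""


class EvidenceError(SodspliceError):
    """Raised when an operation has no evidence to work from."""


class AmbiguityError(SodspliceError):
    """Conflicting evidence that cannot be resolved automatically."""
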