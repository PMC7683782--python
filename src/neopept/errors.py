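"""Exception hierarchy shared across the pipeline stages."""


class NeopeptError(Exception):
    """Base class for all package errors."""


class FormatError(NeopeptError):
    """A file does not conform to its declared format."""


class RecordError(NeopeptError):
    """A single record within an otherwise valid file is invalid."""


class ReferenceMismatchError(NeopeptError):
    """A variant's REF allele disagrees with the genome sequence."""


class UnresolvableOverlapError(NeopeptError):
    """Two events edit overlapping CDS footprints on one transcript."""


class ConfigurationError(NeopeptError):
    """A run configuration or option set is invalid."""


class GenerationError(NeopeptError):
    """A fixture plan is infeasible."""
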