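"""Exception hierarchy shared across the pipeline."""


class FelvarError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FelvarError):
    """Malformed input file (FASTA/VCF/GFF3/PED/TSV syntax or content)."""


class ValidationError(FelvarError):
    """Structurally valid input that violates a data-model invariant."""


class ReferenceMismatchError(FelvarError):
    """Variant REF allele does not match the reference sequence."""


class UnsupportedVariantError(FelvarError):
    """Variant the annotator cannot classify (e.g. spans a CDS/intron boundary)."""


class ConfigurationError(FelvarError):
    """Inconsistent run configuration (unknown sample ids, bad paths, ...)."""


class SizingError(FelvarError):
    """Simulation parameters that do not fit the requested genome."""


class GenerationError(FelvarError):
    """Internal failure while constructing synthetic data."""


class ContractError(FelvarError):
    """An operation was called outside its stated precondition."""
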