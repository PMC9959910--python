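"""Exception hierarchy shared across the pipeline."""


class LFQCohortError(Exception):
    """Base class for all package errors."""


class FormatError(LFQCohortError):
    """A cell or field could not be parsed, or a value is out of range."""


class DuplicateIdError(FormatError):
    """Duplicate protein/peptide or sample identifiers in an input table."""


class ShapeError(FormatError):
    """Input table has too few rows or columns to be meaningful."""


class ConfigError(LFQCohortError):
    """A configuration value is invalid or infeasible."""


class DegenerateSampleError(LFQCohortError):
    """A sample column carries no non-zero intensity."""


class DegenerateInputError(LFQCohortError):
    """Too few usable rows/columns for the requested statistic."""


class InsufficientReplicatesError(LFQCohortError):
    """Fewer QC replicate runs than the statistic requires."""


class InsufficientSamplesError(LFQCohortError):
    """A sample group is too small for the requested statistic."""


class PanelMismatchError(LFQCohortError):
    """No contamination-panel accession is present in the matrix."""


class EmptyQueryError(LFQCohortError):
    """The query set for an enrichment test is empty."""


class TermNotFoundError(LFQCohortError):
    """Annotation term absent from the annotation map."""


class StratificationError(LFQCohortError):
    """Cross-validation folds cannot be stratified (a class is missing)."""
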