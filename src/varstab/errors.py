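"""Exception hierarchy shared across the pipeline stages."""


class VarstabError(Exception):
    """Base class for all package errors."""


class InputError(VarstabError):
    """Empty, undersized, or otherwise unusable input data."""


class ConfigurationError(VarstabError):
    """Missing required columns, bad dialect maps, invalid parameters."""


class ParseError(VarstabError):
    """A malformed token or record that names the offending value."""


class AnnotationGapError(VarstabError):
    """A genomic position falls outside every annotated interval."""


class PanelError(VarstabError):
    """A predictor panel with missing or duplicated tools."""


class MappingError(VarstabError):
    """A raw predictor value not covered by the binarization rules."""


class FrameError(VarstabError):
    """A coding sequence whose length is not a multiple of three."""


class AlphabetError(VarstabError):
    """A nucleotide outside {A, C, G, T}."""


class SynonymyError(VarstabError):
    """An alternative codon that changes the encoded amino acid."""


class GeometryError(VarstabError):
    """Too few or degenerate coordinates for a superposition."""


class SelectionError(VarstabError):
    """An atom selection that matches nothing."""


class TrajectoryIntegrityError(VarstabError):
    """Inconsistent atom identity across trajectory frames."""


class InsufficientDataError(VarstabError):
    """Fewer observations than an estimator requires."""


class NormalizationError(VarstabError):
    """A chase series without a usable t = 0 anchor."""


class MassError(VarstabError):
    """Non-positive total mass where a mass-weighted average is needed."""


class GeneratorSpecError(VarstabError):
    """An inconsistent synthetic-data generator specification."""
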