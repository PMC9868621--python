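"""Exception hierarchy for the profiling pipeline.

All pipeline errors derive from :class:`TcrlikeError` so batch drivers can
isolate per-complex failures without masking programming errors.
"""


class TcrlikeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TcrlikeError):
    """A coordinate or table file could not be parsed."""


class AnnotationError(TcrlikeError):
    """A chain-annotation sidecar is inconsistent with the structure."""


class NumberingError(TcrlikeError):
    """An immunoglobulin chain lacks the required IMGT numbering."""


class PairingError(TcrlikeError):
    """The expected pair of immunoglobulin variable chains is absent."""


class RadiusError(TcrlikeError):
    """An atom's element has no entry in the active van der Waals table."""


class DegenerateGeometryError(TcrlikeError):
    """Too few or collinear reference atoms to define a frame or angle."""


class CurationError(TcrlikeError):
    """Invalid input to the dataset-curation stage."""


class EnergeticsError(TcrlikeError):
    """Invalid or degenerate binding-energy decomposition input."""


class FixtureError(TcrlikeError):
    """A synthetic-fixture specification is unsatisfiable."""
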