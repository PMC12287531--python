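"""Exception hierarchy shared across the pipeline.

Every error raised on bad scientific input derives from
:class:`PhenotargetError` so callers (and the CLI) can catch one base class.
"""


class PhenotargetError(Exception):
    """Base class for all package-specific errors."""


class PlateFormatError(PhenotargetError, ValueError):
    """A plate CSV is malformed (missing/unknown column, bad well address)."""


class PlateIntegrityError(PhenotargetError, ValueError):
    """Duplicate wells or role/field combinations that violate the data model."""


class GroupingError(PhenotargetError, ValueError):
    """A plate group lacks the control or background wells normalization needs."""


class DegeneratePlateError(PhenotargetError, ValueError):
    """Vehicle-control signal does not exceed background; viability undefined."""


class InsufficientDataError(PhenotargetError, ValueError):
    """Too few points / replicates for the requested fit or statistic."""


class CoverageError(PhenotargetError, ValueError):
    """A screening stage requires a measurement that is absent from the table."""


class DegenerateSampleError(PhenotargetError, ValueError):
    """A proteomics sample has zero total intensity and cannot be normalized."""


class UnconvergedFitError(PhenotargetError, RuntimeError):
    """A downstream quantity was requested from a fit that did not converge."""


class UndefinedCDIError(PhenotargetError, ValueError):
    """CDI is undefined because a single-agent viability is zero."""


class InsufficientReplicatesError(PhenotargetError, ValueError):
    """Confidence-bounded synergy volumes require >=2 replicates per cell."""
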