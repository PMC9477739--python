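"""Exception hierarchy for cortexflux.

All package-specific failures derive from :class:`CortexFluxError` so callers
can catch one base class at pipeline boundaries.
"""


class CortexFluxError(Exception):
    """Base class for all cortexflux errors."""


class DomainError(CortexFluxError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateGeometryError(CortexFluxError):
    """Nullcline geometry has collapsed (no bounded regime exists)."""


class NoDominantCompositionError(DegenerateGeometryError):
    """The composition dynamics have no stable interior fixed point."""


class NoNullclineError(CortexFluxError):
    """A binned vector field contains no sign change for the requested rate."""


class EmptyFieldError(CortexFluxError):
    """No bin reached the minimum occupancy required for statistics."""


class EmptySliceError(CortexFluxError):
    """A requested 1-D slice does not intersect any populated bin."""


class EmptyEnsembleError(CortexFluxError):
    """Track generation produced no usable tracks."""


class RankDeficientDesignError(CortexFluxError):
    """Regression design matrix is rank deficient (e.g. single stoichiometry)."""


class TrackFormatError(CortexFluxError):
    """A track table file violates the documented TSV schema."""
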