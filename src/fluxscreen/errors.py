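"""Exception types raised across the package."""


class FluxscreenError(Exception):
    """Base class for package-specific errors."""


class InvalidSpecError(FluxscreenError, ValueError):
    """A library composition or design specification is invalid."""


class InsufficientNTCError(FluxscreenError, ValueError):
    """Not enough non-targeting-control sgRNAs to build a pseudogene."""


class InvalidDesignError(FluxscreenError, ValueError):
    """A screen design is internally inconsistent (e.g. negative doublings)."""


class InvalidParameterError(FluxscreenError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateSampleError(FluxscreenError, ValueError):
    """A sample has zero total signal and cannot be normalized."""


class CannotCenterError(FluxscreenError, ValueError):
    """No NTC sgRNAs survive filtering, so phenotypes cannot be centred."""


class AlignmentError(FluxscreenError, ValueError):
    """Tables that must share an index (e.g. gene universes) do not."""


class CannotThresholdError(FluxscreenError, ValueError):
    """No pseudogenes are available to derive significance thresholds."""


class InsufficientReplicatesError(FluxscreenError, ValueError):
    """Too few in vivo replicates for the requested exclusion."""


class UndefinedCorrelationError(FluxscreenError, ValueError):
    """Fewer than three genes remain, so a correlation is undefined."""


class ConditioningError(FluxscreenError, ValueError):
    """An isotope correction matrix is singular or ill-conditioned."""


class DegenerateStandardError(FluxscreenError, ValueError):
    """The internal-standard channel is zero somewhere."""


class InvalidScheduleError(FluxscreenError, ValueError):
    """A sampling schedule withdraws more medium than is available."""


class LookupError_(FluxscreenError, KeyError):
    """A requested amino acid is missing from a standard curve."""


class InsufficientPointsError(FluxscreenError, ValueError):
    """A regression window contains fewer than three timepoints."""


class UnpairedRecordError(FluxscreenError, ValueError):
    """A competition record set lacks its matched T0 sample."""


class DegenerateReferenceError(FluxscreenError, ValueError):
    """A viability plate has zero T0 luminescence."""


class ParseError(FluxscreenError, ValueError):
    """A sequencing read file is malformed; carries the record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class ConfigError(FluxscreenError, ValueError):
    """A run configuration violates the strict schema."""
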