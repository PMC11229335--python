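"""Exception types shared across the package."""


class CurtainKitError(Exception):
    """Base class for package errors."""


class InvalidParameterError(CurtainKitError, ValueError):
    """A parameter set violates its documented invariants."""


class InputValidationError(CurtainKitError, ValueError):
    """An input array or table fails basic sanity checks."""


class ContractViolationError(CurtainKitError, ValueError):
    """Data passed between stages violates a stated contract."""


class UndefinedVelocityError(CurtainKitError, ValueError):
    """Velocity requested for a track whose start and stop coincide."""


class UndefinedEnrichmentError(CurtainKitError, ZeroDivisionError):
    """Fold enrichment requested against a zero denominator."""


class InsufficientReplicatesError(CurtainKitError, ValueError):
    """A between-strain comparison needs at least two replicates per arm."""
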