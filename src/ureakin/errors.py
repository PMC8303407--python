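"""Exception hierarchy for the urea-kinetics model.

All model-specific failures derive from :class:`KineticsError` so callers
(and the CLI) can catch one base class; the subclasses distinguish the
physically distinct failure modes.
"""


class KineticsError(Exception):
    """Base class for all model errors."""


class InvalidArgumentError(KineticsError, ValueError):
    """An argument violates its precondition (wrong sign, zero duration, ...)."""


class ModelAssumptionError(KineticsError):
    """A derived quantity violates a standing model assumption.

    E.g. the estimated plasma-refilling rate is negative, or meets/exceeds
    the ultrafiltration rate.
    """


class InfeasibleTreatmentError(KineticsError):
    """A compartment volume would become non-positive (ultrafiltration
    exceeds the available fluid)."""


class UnsupportedRegimeError(KineticsError):
    """The characteristic equation has a repeated or complex root; the
    closed-form solution is only provided for two distinct real roots."""


class DegenerateClearanceError(KineticsError):
    """Clearance equals the ultrafiltration rate (K = omega_f), which makes
    the forcing coefficient gamma vanish and the particular solution S/gamma
    undefined."""


class TimeDomainError(KineticsError, ValueError):
    """A time argument lies outside the domain of the requested phase."""


class NoSolutionError(KineticsError):
    """Root finding could not bracket a solution (target concentration
    unattainable for the given single-pool model)."""


class IdentifiabilityWarning(UserWarning):
    """The measurement design is too weak to identify all free parameters."""
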