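"""Exception hierarchy shared across the toolkit."""


class AeropkError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(AeropkError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(AeropkError):
    """Too few usable observations for the requested fit or statistic."""


class DegenerateDistributionError(AeropkError):
    """A fitted distribution is unphysical (e.g. nonpositive probit slope)."""


class UndefinedDistributionError(AeropkError):
    """No sized mass on the impactor stages: the size distribution is undefined."""


class UndefinedRatioError(AeropkError):
    """Denominator of a reported ratio is zero (e.g. emitted dose = 0)."""


class MissingLevelError(AeropkError, KeyError):
    """A requested stress/pressure level is absent from the measured profile."""


class ConfigurationError(AeropkError):
    """A bundled or user-supplied configuration table is incomplete."""


class IntegrationError(AeropkError):
    """The ODE solver failed; carries the last state for diagnosis."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
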