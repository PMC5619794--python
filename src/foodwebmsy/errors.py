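"""Structured errors raised across the pipeline."""


class FoodWebError(Exception):
    """Base class for all package errors."""


class MassBalanceError(FoodWebError):
    """The static mass-balance system cannot be solved.

    Carries the name of the offending group and, where applicable, the
    parameter that came out infeasible.
    """

    def __init__(self, message, group=None, parameter=None):
        super().__init__(message)
        self.group = group
        self.parameter = parameter


class EnergyPartitionError(FoodWebError):
    """Within-group energy budget is infeasible (negative respiration)."""


class CalibrationError(FoodWebError):
    """A trophic link is used before its arena parameters were derived."""


class SimulationError(FoodWebError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message, time=None):
        super().__init__(message)
        self.time = time


class InputError(FoodWebError):
    """Malformed or inconsistent input tables."""

    def __init__(self, message, file=None, row=None):
        super().__init__(message)
        self.file = file
        self.row = row


class MonteCarloError(FoodWebError):
    """Monte Carlo routine exhausted its attempt budget."""

    def __init__(self, message, attempts=None, successes=None):
        super().__init__(message)
        self.attempts = attempts
        self.successes = successes
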